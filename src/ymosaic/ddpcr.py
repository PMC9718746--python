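"""Poisson-corrected digital-droplet PCR quantification of the Y-bearing
cell fraction from the AMELX/AMELY duplex assay.

With random partitioning of template into droplets, the per-droplet copy
number is Poisson, so the mean concentration per droplet is recovered from the
positive-droplet fraction by lambda = -ln(1 - n_positive/n_droplets). Every
genome carries one AMELX copy while only 48,XYYY genomes carry AMELY (three
copies each), so the mosaic fraction is
f_ddpcr = (lambda_AMELY / 3) / lambda_AMELX. Setting the copy-number divisor
to 1 reproduces naive per-allele fractions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import binomtest

from .errors import FormatError, SaturationError

logger = logging.getLogger(__name__)

__all__ = [
    "DdpcrEstimate",
    "read_ddpcr_table",
    "estimate_lambda",
    "estimate_fraction",
]

CHANNELS = ("AMELX", "AMELY")


@dataclass
class DdpcrEstimate:
    """Per-channel concentrations and the derived mosaic-fraction estimate."""

    lambda_x: float
    lambda_x_ci: tuple
    lambda_y: float
    lambda_y_ci: tuple
    f_ddpcr: float
    f_ci: tuple
    y_copies_per_positive_cell: float
    n_droplets: dict
    clamped: bool = False

    def to_dict(self) -> dict:
        return {
            "lambda_AMELX": self.lambda_x,
            "lambda_AMELX_ci": list(self.lambda_x_ci),
            "lambda_AMELY": self.lambda_y,
            "lambda_AMELY_ci": list(self.lambda_y_ci),
            "f_ddpcr": self.f_ddpcr,
            "f_ddpcr_ci": list(self.f_ci),
            "y_copies_per_positive_cell": self.y_copies_per_positive_cell,
            "n_droplets": self.n_droplets,
            "clamped": self.clamped,
        }


def read_ddpcr_table(path) -> pd.DataFrame:
    """Read a droplet-count TSV with columns well, channel, n_droplets, n_positive."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"well", "channel", "n_droplets", "n_positive"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: ddPCR table needs columns {sorted(need)}")
    if (df["n_droplets"] <= 0).any():
        raise FormatError("n_droplets must be positive")
    if ((df["n_positive"] < 0) | (df["n_positive"] > df["n_droplets"])).any():
        raise FormatError("n_positive must lie in [0, n_droplets]")
    bad = set(df["channel"]) - set(CHANNELS)
    if bad:
        raise FormatError(f"unknown channels {sorted(bad)}; expected {CHANNELS}")
    return df


def estimate_lambda(n_droplets: int, n_positive: int, confidence: float = 0.95):
    """Poisson concentration per droplet from the positive fraction.

    lambda = -ln(1 - p_hat); the CI maps the Clopper-Pearson binomial CI on
    the positive fraction through the same transform. Raises
    :class:`SaturationError` when every droplet is positive.
    """
    if n_positive >= n_droplets:
        raise SaturationError(
            f"{n_positive}/{n_droplets} droplets positive: lambda is unbounded"
        )
    p_hat = n_positive / n_droplets
    lam = -math.log(1.0 - p_hat)
    ci = binomtest(n_positive, n_droplets).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    lo = -math.log(1.0 - ci.low)
    hi = -math.log(1.0 - ci.high) if ci.high < 1.0 else math.inf
    return lam, (lo, hi)


def estimate_fraction(
    wells: pd.DataFrame, y_copies_per_positive_cell: float = 3.0
) -> DdpcrEstimate:
    """Mosaic fraction from pooled AMELX/AMELY wells.

    Wells are pooled by summing droplets per channel before the Poisson
    inversion (merged-well estimator; lower variance than averaging per-well
    concentrations). The CI on f combines the channel CIs conservatively:
    [lo_Y/hi_X, hi_Y/lo_X] / copies, clamped to [0, 1].
    """
    present = set(wells["channel"])
    missing = set(CHANNELS) - present
    if missing:
        raise FormatError(f"missing ddPCR channel(s): {sorted(missing)}")
    pooled = wells.groupby("channel")[["n_droplets", "n_positive"]].sum()

    lam_x, ci_x = estimate_lambda(
        int(pooled.loc["AMELX", "n_droplets"]), int(pooled.loc["AMELX", "n_positive"])
    )
    lam_y, ci_y = estimate_lambda(
        int(pooled.loc["AMELY", "n_droplets"]), int(pooled.loc["AMELY", "n_positive"])
    )
    if lam_x <= 0:
        raise FormatError("AMELX concentration is zero; cannot normalize")

    c = y_copies_per_positive_cell
    f_raw = (lam_y / c) / lam_x
    f = min(1.0, max(0.0, f_raw))
    clamped = f != f_raw
    if clamped:
        logger.info("f_ddpcr %.4f clamped into [0,1]", f_raw)
    lo = (ci_y[0] / c) / ci_x[1] if ci_x[1] > 0 else 0.0
    hi = (ci_y[1] / c) / ci_x[0] if ci_x[0] > 0 else math.inf
    f_ci = (min(1.0, max(0.0, lo)), min(1.0, hi))
    return DdpcrEstimate(
        lambda_x=lam_x,
        lambda_x_ci=ci_x,
        lambda_y=lam_y,
        lambda_y_ci=ci_y,
        f_ddpcr=f,
        f_ci=f_ci,
        y_copies_per_positive_cell=c,
        n_droplets={ch: int(pooled.loc[ch, "n_droplets"]) for ch in CHANNELS},
        clamped=clamped,
    )
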