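"""Per-cell karyotype calling from Y-linked expression and mosaic-fraction
estimation with dropout correction.

A cell is called 48,XYYY when its UMI total over the non-PAR Y gene panel
reaches ``min_y_umi`` (default 1: any single Y-linked UMI), otherwise 45,X —
the complete-absence rule. Because a truly Y-bearing cell can show zero Y
UMIs by sampling dropout, the observed XYYY fraction f_obs underestimates the
true fraction by a factor (1 - q), where q is the zero-Y probability of a
Y-bearing cell. q is estimated from a reference in which every cell carries Y,
and the corrected fraction is f_hat = f_obs / (1 - q), clamped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .annotation_io import CountMatrix, GenePanel
from .errors import ConfigurationError, EmptyResultError

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCallSet",
    "FalseNegativeRate",
    "call_genotype",
    "estimate_false_negative_rate",
    "correct_mosaic_fraction",
    "apply_fnr_correction",
]

CALL_X = "45,X"
CALL_XYYY = "48,XYYY"


@dataclass
class GenotypeCallSet:
    """Binary per-cell karyotype calls plus mosaic-fraction estimates."""

    calls: pd.DataFrame  # barcode, call, y_umi
    min_y_umi: int
    n_x: int
    n_xyyy: int
    f_obs: float
    q: float = 0.0  # false-negative (zero-Y dropout) rate used for correction
    f_hat: float | None = None
    f_hat_ci: tuple | None = None

    def __post_init__(self):
        if self.f_hat is None:
            self.f_hat = self.f_obs
        assert self.n_x + self.n_xyyy == len(self.calls)
        for v in (self.f_obs, self.f_hat, self.q):
            assert -1e-12 <= v <= 1 + 1e-12

    def summary(self) -> dict:
        return {
            "n_cells": int(self.n_x + self.n_xyyy),
            "n_45X": int(self.n_x),
            "n_48XYYY": int(self.n_xyyy),
            "f_obs": float(self.f_obs),
            "f_hat": float(self.f_hat),
            "q": float(self.q),
            "f_hat_ci": list(self.f_hat_ci) if self.f_hat_ci else None,
            "min_y_umi": int(self.min_y_umi),
        }


@dataclass
class FalseNegativeRate:
    """Zero-Y dropout rate estimated from an all-Y-bearing reference."""

    q: float
    ci: tuple
    n_reference: int
    n_zero_y: int


def call_genotype(counts: CountMatrix, panel: GenePanel, min_y_umi: int = 1) -> GenotypeCallSet:
    """Call every cell 48,XYYY (>= min_y_umi Y-panel UMIs) or 45,X (fewer).

    Every cell receives a call; there is no ambiguous class. The default
    min_y_umi=1 implements presence-vs-complete-absence of Y-linked expression.
    """
    if not panel.y_genes:
        raise ConfigurationError("empty Y panel")
    if counts.n_cells == 0:
        raise EmptyResultError("no cells to genotype")
    if min_y_umi < 1:
        raise ConfigurationError("min_y_umi must be >= 1")
    y_umi = counts.sum_over_genes(panel.y_genes)
    is_xyyy = y_umi >= min_y_umi
    calls = pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "call": np.where(is_xyyy, CALL_XYYY, CALL_X),
            "y_umi": y_umi,
        }
    )
    n_xyyy = int(is_xyyy.sum())
    n_x = int(counts.n_cells - n_xyyy)
    return GenotypeCallSet(
        calls=calls,
        min_y_umi=min_y_umi,
        n_x=n_x,
        n_xyyy=n_xyyy,
        f_obs=n_xyyy / counts.n_cells,
    )


def estimate_false_negative_rate(
    reference_counts: CountMatrix, panel: GenePanel, min_y_umi: int = 1
) -> FalseNegativeRate:
    """Estimate the zero-Y dropout rate q from a reference where every cell
    carries chromosome Y (e.g. a healthy-male PBMC profile or a matched
    all-XYYY simulation).

    q is the fraction of reference cells whose Y-panel UMI total falls below
    min_y_umi, with a Clopper-Pearson 95% CI.
    """
    n = reference_counts.n_cells
    if n == 0:
        raise EmptyResultError("empty reference")
    if n < 100:
        logger.warning(
            "false-negative reference has only %d cells; CI will be wide", n
        )
    y_umi = reference_counts.sum_over_genes(panel.y_genes)
    k = int((y_umi < min_y_umi).sum())
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return FalseNegativeRate(q=k / n, ci=(ci.low, ci.high), n_reference=n, n_zero_y=k)


def correct_mosaic_fraction(f_obs: float, q: float) -> float:
    """Dropout-corrected mosaic fraction f_hat = min(1, f_obs / (1 - q)).

    Assumes false positives are negligible (no ambient Y contamination).
    Identity when q = 0.
    """
    if not 0.0 <= f_obs <= 1.0:
        raise ValueError(f"f_obs={f_obs} outside [0,1]")
    if not 0.0 <= q < 1.0:
        raise ValueError(f"q={q} must lie in [0,1)")
    return min(1.0, f_obs / (1.0 - q))


def apply_fnr_correction(
    callset: GenotypeCallSet,
    fnr: FalseNegativeRate,
    n_boot: int = 500,
    seed: int = 0,
) -> GenotypeCallSet:
    """Attach the dropout-corrected fraction and a bootstrap 95% CI.

    The bootstrap resamples both the binomial call count and the binomial
    reference zero-Y count, propagating both sources of sampling noise.
    """
    n = callset.n_x + callset.n_xyyy
    f_hat = correct_mosaic_fraction(callset.f_obs, fnr.q)
    rng = np.random.default_rng(seed)
    f_b = rng.binomial(n, callset.f_obs, size=n_boot) / n
    q_b = rng.binomial(fnr.n_reference, fnr.q, size=n_boot) / fnr.n_reference
    q_b = np.minimum(q_b, 0.999)
    fhat_b = np.minimum(1.0, f_b / (1.0 - q_b))
    lo, hi = np.percentile(fhat_b, [2.5, 97.5])
    return GenotypeCallSet(
        calls=callset.calls,
        min_y_umi=callset.min_y_umi,
        n_x=callset.n_x,
        n_xyyy=callset.n_xyyy,
        f_obs=callset.f_obs,
        q=fnr.q,
        f_hat=f_hat,
        f_hat_ci=(float(lo), float(hi)),
    )
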