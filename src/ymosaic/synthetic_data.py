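"""Synthetic mosaic-PBMC UMI matrices and ddPCR droplet counts with ground truth.

The generator emulates a peripheral-blood sample that is a mosaic of two
lineages: 45,X (no Y chromosome) and 48,XYYY (one X, three Y). Cells belong to
eight immune cell types whose lineage composition may differ; Y-linked gene
means scale with Y copy number (zero in 45,X cells), X-linked and autosomal
means are lineage-invariant. Counts follow a gamma-Poisson (negative binomial)
model with log-normal library sizes, so dropout arises naturally from low
means. Optional knobs plant ambient Y contamination, low-quality cells and
lineage-differential autosomal genes, each recorded in the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse

from .annotation_io import CountMatrix, write_mtx_triplet
from .errors import ConfigurationError

__all__ = [
    "SimConfig",
    "SimTruth",
    "DdpcrSimConfig",
    "simulate_pbmc",
    "simulate_ddpcr",
    "write_simulation",
]

LINEAGE_X = "45,X"
LINEAGE_XYYY = "48,XYYY"

# Eight major immune cell types with realistic PBMC proportions, and default
# per-type 48,XYYY fractions following the observed pattern: T cells skewed
# towards the triple-Y lineage, B cells and monocytes towards 45,X. The
# proportion-weighted global fraction is 0.484.
DEFAULT_CELL_TYPES: dict[str, float] = {
    "CD4+ T cells": 0.30,
    "CD8+ T cells": 0.15,
    "NK cells": 0.10,
    "B cells": 0.12,
    "Classical monocytes": 0.20,
    "Non-classical monocytes": 0.05,
    "Dendritic cells": 0.03,
    "Other": 0.05,
}

DEFAULT_LINEAGE_FRACTIONS: dict[str, float] = {
    "CD4+ T cells": 0.60,
    "CD8+ T cells": 0.60,
    "NK cells": 0.50,
    "B cells": 0.30,
    "Classical monocytes": 0.34,
    "Non-classical monocytes": 0.40,
    "Dendritic cells": 0.50,
    "Other": 0.50,
}


@dataclass
class SimConfig:
    """Parameters of the mosaic-PBMC simulator.

    The defaults mirror the study conditions: ~3000 cells of which 64 planted
    low-quality (leaving 2936 after QC), median library 7400 UMIs, eight
    immune cell types with a global 48,XYYY fraction of 0.484, and a three-Y
    lineage whose Y-gene means are 3x a single-copy baseline.
    """

    seed: int
    n_cells: int = 3000
    cell_types: dict = field(default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    lineage_fractions: dict | None = field(
        default_factory=lambda: dict(DEFAULT_LINEAGE_FRACTIONS)
    )
    f: float = 0.4843  # global XYYY fraction, used when lineage_fractions is None
    n_autosomal: int = 1000
    n_x: int = 40
    n_y: int = 12
    n_par: int = 6
    n_mt: int = 10
    gene_logmean_sigma: float = 1.2  # spread of relative gene weights (log-normal)
    library_median_umi: float = 7400.0
    library_logsigma: float = 0.35
    y_dosage_multiplier: float = 3.0  # Y-gene mean scaling per XYYY cell
    y_base_mean: float | None = None  # per-Y-gene mean at 1 copy & median library
    dispersion: float = 0.3  # NB dispersion alpha (var = mu + alpha*mu^2); 0 = Poisson
    ambient_y_rate: float = 0.0  # expected spurious Y UMIs per cell
    n_low_quality: int = 64
    low_quality_umi: float = 120.0
    n_de_genes: int = 0  # planted lineage-differential autosomal genes
    de_log2fc: float = 2.0

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory for reproducibility")
        if not 0.0 <= self.f <= 1.0:
            raise ConfigurationError(f"global lineage fraction f={self.f} outside [0,1]")
        if self.lineage_fractions is not None:
            for name, fc in self.lineage_fractions.items():
                if not 0.0 <= fc <= 1.0:
                    raise ConfigurationError(
                        f"lineage fraction for {name!r} = {fc} outside [0,1]"
                    )
        if self.y_dosage_multiplier <= 0:
            raise ConfigurationError("y_dosage_multiplier must be > 0")
        if self.ambient_y_rate < 0:
            raise ConfigurationError("ambient_y_rate must be >= 0")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if abs(sum(self.cell_types.values()) - 1.0) > 1e-8:
            raise ConfigurationError("cell type proportions must sum to 1")
        if self.n_y < 1:
            raise ConfigurationError("need at least one Y gene")
        if self.n_de_genes > self.n_autosomal:
            raise ConfigurationError("n_de_genes exceeds autosomal catalogue")


@dataclass
class SimTruth:
    """Ground truth of one simulation: per-cell assignments and parameters."""

    cells: pd.DataFrame  # barcode, lineage, cell_type, library_size, low_quality
    annotations: pd.DataFrame  # gene_id, symbol, chromosome, start, end, par
    gene_means: pd.DataFrame  # gene_id, relative_weight, base_mean_at_median_library
    de_genes: pd.DataFrame  # gene_id, direction ("up_in_48,XYYY" / "up_in_45,X")
    realized_fractions: pd.DataFrame  # cell_type, n_cells, n_xyyy, fraction
    config: SimConfig

    @property
    def global_fraction(self) -> float:
        return float((self.cells["lineage"] == LINEAGE_XYYY).mean())


def _gene_catalogue(cfg: SimConfig, rng: np.random.Generator):
    """Build the simulated gene annotation table.

    PAR genes are placed inside GRCh38 PAR1 so that coordinate-based PAR
    flagging reproduces the truth; autosomes are assigned round-robin.
    """
    rows = []
    autosomes = [str(c) for c in range(1, 23)]
    for i in range(cfg.n_autosomal):
        rows.append(("AUTO", autosomes[i % 22], i))
    for i in range(cfg.n_x):
        rows.append(("X", "X", i))
    for i in range(cfg.n_y):
        rows.append(("Y", "Y", i))
    for i in range(cfg.n_par):
        rows.append(("PAR", "X" if i % 2 == 0 else "Y", i))
    for i in range(cfg.n_mt):
        rows.append(("MT", "MT", i))

    records = []
    for j, (kind, chrom, i) in enumerate(rows):
        gene_id = f"SIMG{j:05d}"
        if kind == "MT":
            symbol = f"MT-SYN{i + 1}"
        else:
            symbol = f"{kind}SYN{i + 1}"
        if kind == "PAR":
            start = 20001 + 1000 * i  # inside PAR1 on either sex chromosome
        elif chrom in ("X", "Y"):
            start = 3_000_000 + 10_000 * i  # outside both PARs
        else:
            start = 1_000_000 + 1000 * i
        records.append(
            {
                "gene_id": gene_id,
                "symbol": symbol,
                "chromosome": chrom,
                "start": start,
                "end": start + 500,
                "par": kind == "PAR",
                "kind": kind,
            }
        )
    return pd.DataFrame(records)


def simulate_pbmc(cfg: SimConfig):
    """Simulate a mosaic PBMC UMI matrix.

    Returns ``(CountMatrix, cells, truth)`` where ``cells`` is the per-cell
    label table (barcode, cell_type) and ``truth`` the full ground truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells

    type_names = list(cfg.cell_types)
    props = np.array([cfg.cell_types[t] for t in type_names], dtype=float)
    cell_type = rng.choice(type_names, size=n, p=props / props.sum())

    if cfg.lineage_fractions is not None:
        missing = set(type_names) - set(cfg.lineage_fractions)
        if missing:
            raise ConfigurationError(f"lineage_fractions missing types {sorted(missing)}")
        fc = np.array([cfg.lineage_fractions[t] for t in cell_type])
    else:
        fc = np.full(n, cfg.f)
    is_xyyy = rng.random(n) < fc

    genes = _gene_catalogue(cfg, rng)
    n_genes = len(genes)
    weights = rng.lognormal(mean=0.0, sigma=cfg.gene_logmean_sigma, size=n_genes)

    y_mask = ((genes["chromosome"] == "Y") & (~genes["par"])).to_numpy()
    x_mask = ((genes["chromosome"] == "X") & (~genes["par"])).to_numpy()

    if cfg.y_base_mean is not None:
        # Pin each non-PAR Y gene's single-copy mean at the median library,
        # leaving the rest of the catalogue's relative structure untouched.
        p_y = cfg.y_base_mean / cfg.library_median_umi
        if p_y * y_mask.sum() >= 1.0:
            raise ConfigurationError("y_base_mean too large for library size")
        rest = ~y_mask
        weights[rest] *= (1.0 - p_y * y_mask.sum()) / weights[rest].sum()
        weights[y_mask] = p_y
        p = weights
    else:
        p = weights / weights.sum()

    lib = rng.lognormal(mean=math.log(cfg.library_median_umi), sigma=cfg.library_logsigma, size=n)
    low_quality = np.zeros(n, dtype=bool)
    if cfg.n_low_quality > 0:
        lowq_idx = rng.choice(n, size=cfg.n_low_quality, replace=False)
        low_quality[lowq_idx] = True
        lib[lowq_idx] = cfg.low_quality_umi

    # per-cell x per-gene NB means
    mu = lib[:, None] * p[None, :]
    dosage = np.where(is_xyyy, cfg.y_dosage_multiplier, 0.0)
    mu[:, y_mask] *= dosage[:, None]

    de_rows = []
    if cfg.n_de_genes > 0:
        auto_idx = np.flatnonzero((genes["kind"] == "AUTO").to_numpy())
        de_idx = rng.choice(auto_idx, size=cfg.n_de_genes, replace=False)
        fold = 2.0 ** cfg.de_log2fc
        for k, gi in enumerate(de_idx):
            if k % 2 == 0:  # up in the triple-Y lineage
                mu[is_xyyy, gi] *= fold
                de_rows.append({"gene_id": genes.at[gi, "gene_id"], "direction": f"up_in_{LINEAGE_XYYY}"})
            else:
                mu[~is_xyyy, gi] *= fold
                de_rows.append({"gene_id": genes.at[gi, "gene_id"], "direction": f"up_in_{LINEAGE_X}"})
    de_genes = pd.DataFrame(de_rows, columns=["gene_id", "direction"])

    if cfg.dispersion > 0:
        # gamma-Poisson: lam ~ Gamma(shape=1/alpha, scale=mu*alpha) gives
        # E=mu, Var=mu+alpha*mu^2 after Poisson sampling
        shape = 1.0 / cfg.dispersion
        lam = np.zeros_like(mu)
        pos = mu > 0
        lam[pos] = rng.gamma(shape, mu[pos] * cfg.dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    if cfg.ambient_y_rate > 0:
        n_y_genes = int(y_mask.sum())
        amb = rng.poisson(cfg.ambient_y_rate / n_y_genes, size=(n, n_y_genes))
        counts[:, np.flatnonzero(y_mask)] += amb

    barcodes = np.array([f"CELL{i:05d}-1" for i in range(n)], dtype=object)
    cm = CountMatrix(
        barcodes=barcodes,
        genes=genes[["gene_id", "symbol"]].copy(),
        counts=sparse.csr_matrix(counts),
    )
    cells = pd.DataFrame({"barcode": barcodes, "cell_type": cell_type})

    lineage = np.where(is_xyyy, LINEAGE_XYYY, LINEAGE_X)
    truth_cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "lineage": lineage,
            "cell_type": cell_type,
            "library_size": lib,
            "low_quality": low_quality,
        }
    )
    realized = (
        truth_cells.assign(xyyy=is_xyyy)
        .groupby("cell_type", sort=True)
        .agg(n_cells=("xyyy", "size"), n_xyyy=("xyyy", "sum"))
        .reset_index()
    )
    realized["fraction"] = realized["n_xyyy"] / realized["n_cells"]
    gene_means = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "relative_weight": p,
            "base_mean_at_median_library": p * cfg.library_median_umi,
        }
    )
    truth = SimTruth(
        cells=truth_cells,
        annotations=genes[["gene_id", "symbol", "chromosome", "start", "end", "par"]].copy(),
        gene_means=gene_means,
        de_genes=de_genes,
        realized_fractions=realized,
        config=cfg,
    )
    return cm, cells, truth


# ---------------------------------------------------------------------------
# ddPCR simulation


@dataclass
class DdpcrSimConfig:
    """Duplex AMELX/AMELY droplet-partitioning simulator parameters.

    ``lambda_gdna`` is the mean number of genome equivalents per droplet. Every
    genome carries one AMELX copy; a fraction ``f`` of genomes (the 48,XYYY
    lineage) carries ``y_copies_per_genome`` AMELY copies, the rest zero.
    """

    seed: int
    n_droplets: int = 20000
    lambda_gdna: float = 0.5
    f: float = 0.4843
    y_copies_per_genome: int = 3
    n_wells: int = 4

    def validate(self) -> None:
        if self.lambda_gdna <= 0:
            raise ConfigurationError("lambda_gdna must be > 0")
        if not 0.0 <= self.f <= 1.0:
            raise ConfigurationError(f"f={self.f} outside [0,1]")
        if self.n_droplets < 1 or self.n_wells < 1:
            raise ConfigurationError("need >=1 droplet and >=1 well")


def simulate_ddpcr(cfg: DdpcrSimConfig) -> pd.DataFrame:
    """Simulate per-well droplet counts for the AMELX/AMELY duplex assay.

    A droplet is positive in a channel when it received >=1 target copy;
    with Poisson loading the positive probability is 1 - exp(-lambda_channel),
    lambda_AMELX = lambda_gdna and lambda_AMELY = lambda_gdna * y_copies * f.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lam = {
        "AMELX": cfg.lambda_gdna,
        "AMELY": cfg.lambda_gdna * cfg.y_copies_per_genome * cfg.f,
    }
    rows = []
    for w in range(1, cfg.n_wells + 1):
        for channel in ("AMELX", "AMELY"):
            p_pos = 1.0 - math.exp(-lam[channel])
            n_pos = int(rng.binomial(cfg.n_droplets, p_pos))
            rows.append(
                {
                    "well": f"W{w:02d}",
                    "channel": channel,
                    "n_droplets": cfg.n_droplets,
                    "n_positive": n_pos,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# emission


def write_simulation(outdir, cm: CountMatrix, cells: pd.DataFrame, truth: SimTruth) -> dict:
    """Emit a simulation as MTX triplet + label/annotation/truth TSVs + config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "barcodes": outdir / "barcodes.tsv",
        "features": outdir / "features.tsv",
        "cell_types": outdir / "cell_types.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.yaml",
    }
    write_mtx_triplet(cm, paths["matrix"], paths["barcodes"], paths["features"])
    cells.to_csv(paths["cell_types"], sep="\t", index=False)
    truth.annotations.to_csv(paths["annotation"], sep="\t", index=False)
    truth.cells.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(truth.config), fh, sort_keys=False)
    return {k: str(v) for k, v in paths.items()}
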