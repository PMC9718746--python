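"""Per-cell-type differential expression between the 45,X and 48,XYYY lineages.

Counts are log-normalized per cell (ln(1 + count/total * 10^4), the standard
single-cell recipe), genes detected in at least ``min_frac_expressing`` of
either genotype group are tested with a two-sided Wilcoxon rank-sum test
(normal approximation with tie correction at scale; exact for tiny tie-free
samples), and p-values are Bonferroni-adjusted over the genes tested in that
comparison. Genes on a curated hematological-malignancy list can be flagged.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import mannwhitneyu

from .annotation_io import CountMatrix
from .errors import ConfigurationError
from .genotyping import CALL_X, CALL_XYYY, GenotypeCallSet

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_counts",
    "rank_sum_test",
    "de_test",
    "de_test_all",
    "flag_malignancy_genes",
    "default_malignancy_list",
]

DE_COLUMNS = [
    "cell_type",
    "gene_id",
    "symbol",
    "chromosome",
    "mean_45X",
    "mean_48XYYY",
    "log2fc",
    "p_value",
    "p_bonferroni",
    "direction",
    "malignancy_flag",
]


def normalize_counts(counts: CountMatrix, scale_factor: float = 1e4) -> sparse.csr_matrix:
    """Per-cell log normalization: ln(1 + count / cell_total * scale_factor).

    Returns a sparse cells x genes float matrix (zeros stay zero). Cells with
    zero total are rejected — they should have been removed by QC.
    """
    totals = np.asarray(counts.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-total cell encountered; run qc_filter first")
    mat = counts.counts.tocoo().astype(float)
    mat.data = np.log1p(mat.data / totals[mat.row] * scale_factor)
    return mat.tocsr()


def rank_sum_test(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    method="auto" uses the exact null distribution for small tie-free samples
    and the tie-corrected normal approximation otherwise (scipy semantics).
    """
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def de_test(
    counts: CountMatrix,
    calls: GenotypeCallSet,
    cells: pd.DataFrame,
    target_type: str,
    normalized: sparse.csr_matrix | None = None,
    annotations: pd.DataFrame | None = None,
    min_frac_expressing: float = 0.1,
    alpha: float = 0.05,
    min_cells: int = 20,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Rank-sum DE between genotype lineages within one cell type.

    Only genes expressed in >= ``min_frac_expressing`` of either group are
    tested; Bonferroni multiplies by the number of genes actually tested.
    Returns a DataFrame (columns ``DE_COLUMNS``), sorted by adjusted p; with
    ``significant_only`` the table is restricted to adjusted p < alpha.
    Returns an empty table (with a logged warning) when either genotype group
    has fewer than ``min_cells`` cells of the target type.
    """
    if normalized is None:
        normalized = normalize_counts(counts)
    merged = cells.merge(calls.calls[["barcode", "call"]], on="barcode")
    order = pd.Index(counts.barcodes)
    merged = merged.set_index("barcode").loc[order].reset_index()
    in_type = (merged["cell_type"] == target_type).to_numpy()
    g_x = in_type & (merged["call"] == CALL_X).to_numpy()
    g_y = in_type & (merged["call"] == CALL_XYYY).to_numpy()
    if g_x.sum() < min_cells or g_y.sum() < min_cells:
        logger.warning(
            "cell type %r skipped: %d 45,X / %d 48,XYYY cells (< %d)",
            target_type, int(g_x.sum()), int(g_y.sum()), min_cells,
        )
        return pd.DataFrame(columns=DE_COLUMNS)

    ax = np.asarray(normalized[g_x].todense())
    ay = np.asarray(normalized[g_y].todense())
    frac_x = (ax > 0).mean(axis=0)
    frac_y = (ay > 0).mean(axis=0)
    tested = (frac_x >= min_frac_expressing) | (frac_y >= min_frac_expressing)
    m = int(tested.sum())
    if m == 0:
        return pd.DataFrame(columns=DE_COLUMNS)

    res = mannwhitneyu(
        ax[:, tested], ay[:, tested], alternative="two-sided", method="asymptotic", axis=0
    )
    p = np.asarray(res.pvalue, dtype=float)
    p_bonf = np.minimum(1.0, p * m)

    mean_x = ax[:, tested].mean(axis=0)
    mean_y = ay[:, tested].mean(axis=0)
    # fold change on the de-logged per-10k scale with pseudocount 1
    log2fc = np.log2((np.expm1(ay[:, tested]).mean(axis=0) + 1.0)
                     / (np.expm1(ax[:, tested]).mean(axis=0) + 1.0))

    genes = counts.genes.loc[tested, ["gene_id", "symbol"]].reset_index(drop=True)
    if annotations is not None:
        chrom = genes.merge(
            annotations[["gene_id", "chromosome"]], on="gene_id", how="left"
        )["chromosome"]
    else:
        chrom = pd.Series([""] * m)
    out = pd.DataFrame(
        {
            "cell_type": target_type,
            "gene_id": genes["gene_id"],
            "symbol": genes["symbol"],
            "chromosome": chrom.fillna(""),
            "mean_45X": mean_x,
            "mean_48XYYY": mean_y,
            "log2fc": log2fc,
            "p_value": p,
            "p_bonferroni": p_bonf,
            "direction": np.where(log2fc >= 0, f"up_in_{CALL_XYYY}", f"up_in_{CALL_X}"),
            "malignancy_flag": False,
        }
    )
    if significant_only:
        out = out[out["p_bonferroni"] < alpha]
    return out.sort_values("p_bonferroni", kind="mergesort").reset_index(drop=True)


def de_test_all(
    counts: CountMatrix,
    calls: GenotypeCallSet,
    cells: pd.DataFrame,
    mode: str = "per_type",
    **kwargs,
) -> pd.DataFrame:
    """DE across comparisons.

    mode="per_type" runs one lineage comparison inside each cell type and
    concatenates; mode="aggregate" runs a single comparison pooling all cells
    (cell type set to "all").
    """
    normalized = kwargs.pop("normalized", None)
    if normalized is None:
        normalized = normalize_counts(counts)
    if mode == "aggregate":
        pooled = cells.copy()
        pooled["cell_type"] = "all"
        return de_test(counts, calls, pooled, "all", normalized=normalized, **kwargs)
    if mode != "per_type":
        raise ValueError(f"unknown mode {mode!r}")
    frames = []
    for ct in sorted(cells["cell_type"].unique()):
        res = de_test(counts, calls, cells, ct, normalized=normalized, **kwargs)
        if not res.empty:
            frames.append(res)
    if not frames:
        return pd.DataFrame(columns=DE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def default_malignancy_list():
    """Path-like handle to the packaged curated hematological-malignancy genes."""
    return resources.files("ymosaic.data").joinpath("malignancy_genes.tsv")


def flag_malignancy_genes(results: pd.DataFrame, gene_list_path=None) -> pd.DataFrame:
    """Flag DE genes on the curated hematological-malignancy list.

    Mutates the ``malignancy_flag`` column of a copy of ``results`` and
    returns the flagged subset (the full annotated table is attached as
    ``.attrs["annotated"]``).
    """
    if gene_list_path is None:
        with default_malignancy_list().open() as fh:
            lst = pd.read_csv(fh, sep="\t")
    else:
        lst = pd.read_csv(gene_list_path, sep="\t")
    if lst.empty or "symbol" not in lst.columns:
        raise ConfigurationError(f"malignancy gene list {gene_list_path} empty or malformed")
    symbols = set(lst["symbol"].astype(str))
    annotated = results.copy()
    if annotated.empty:
        annotated["malignancy_flag"] = pd.Series(dtype=bool)
        flagged = annotated
    else:
        annotated["malignancy_flag"] = annotated["symbol"].isin(symbols)
        flagged = annotated[annotated["malignancy_flag"]].reset_index(drop=True)
    flagged.attrs["annotated"] = annotated
    return flagged
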