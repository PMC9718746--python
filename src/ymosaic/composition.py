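"""Monte Carlo permutation test for genotype composition across cell types.

The question: do the per-cell-type 48,XYYY fractions differ from the pooled
fraction beyond what random assignment of the same genotype totals to the same
type sizes would produce? The two-sided statistic per type c is
T_c = |p_c - p_bar| with p_c the type's XYYY fraction and p_bar the pooled
fraction. The null is generated by redistributing the observed genotype
multiset across cells while preserving each type's size, which is exactly a
multivariate hypergeometric draw of the XYYY total over the type sizes.
P-values use the add-one estimator (b+1)/(n_perm+1); Benjamini-Hochberg
controls the FDR across cell types.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import JoinError
from .genotyping import CALL_XYYY, GenotypeCallSet

__all__ = [
    "CompositionResult",
    "composition_fractions",
    "permutation_test_composition",
    "exact_enumeration_test",
]


@dataclass
class CompositionResult:
    """Per-cell-type genotype composition with permutation p/q-values."""

    table: pd.DataFrame  # cell_type, n_cells, n_xyyy, fraction, p_value, q_value, significant
    pooled_fraction: float
    n_perm: int
    seed: int | None
    alpha: float


def _join_calls(cells: pd.DataFrame, calls: GenotypeCallSet) -> pd.DataFrame:
    call_df = calls.calls[["barcode", "call"]]
    left_only = set(cells["barcode"]) - set(call_df["barcode"])
    right_only = set(call_df["barcode"]) - set(cells["barcode"])
    if left_only or right_only:
        offenders = sorted(left_only | right_only)
        raise JoinError(
            f"{len(offenders)} barcodes present in only one of cell table / "
            f"call set (first: {offenders[:5]})",
            offenders=offenders,
        )
    merged = cells.merge(call_df, on="barcode", how="inner")
    merged["xyyy"] = merged["call"] == CALL_XYYY
    return merged


def composition_fractions(
    cells: pd.DataFrame, calls: GenotypeCallSet, min_cells: int = 20
) -> pd.DataFrame:
    """Exact per-type genotype counts and fractions; types below ``min_cells``
    are flagged low-n (they stay in the table and the test)."""
    merged = _join_calls(cells, calls)
    tab = (
        merged.groupby("cell_type", sort=True)
        .agg(n_cells=("xyyy", "size"), n_xyyy=("xyyy", "sum"))
        .reset_index()
    )
    tab["n_xyyy"] = tab["n_xyyy"].astype(int)
    tab["fraction"] = tab["n_xyyy"] / tab["n_cells"]
    tab["low_n"] = tab["n_cells"] < min_cells
    return tab


def _observed_stats(tab: pd.DataFrame):
    """Integer-exact two-sided statistics: T_c proportional to |x_c*N - X*n_c|."""
    n_c = tab["n_cells"].to_numpy(dtype=np.int64)
    x_c = tab["n_xyyy"].to_numpy(dtype=np.int64)
    N = int(n_c.sum())
    X = int(x_c.sum())
    t_obs = np.abs(x_c * N - X * n_c)  # == n_c*N*|p_c - p_bar|, but exact
    return n_c, x_c, N, X, t_obs


def permutation_test_composition(
    cells: pd.DataFrame,
    calls: GenotypeCallSet,
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
    min_cells: int = 20,
) -> CompositionResult:
    """Monte Carlo permutation test of per-type genotype composition.

    Shuffling genotype labels across all cells while keeping each type's size
    is equivalent to drawing the per-type XYYY counts from a multivariate
    hypergeometric distribution, which is what is sampled here (vectorized).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm={n_perm} too small for meaningful p-values (need >=100)")
    tab = composition_fractions(cells, calls, min_cells=min_cells)
    if len(tab) < 2:
        raise ValueError("need at least two cell types")
    n_c, x_c, N, X, t_obs = _observed_stats(tab)

    rng = np.random.default_rng(seed)
    perm_counts = rng.multivariate_hypergeometric(n_c, X, size=n_perm)
    t_perm = np.abs(perm_counts * N - X * n_c[None, :])
    b = (t_perm >= t_obs[None, :]).sum(axis=0)
    p = (b + 1) / (n_perm + 1)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = tab.copy()
    out["p_value"] = p
    out["q_value"] = q
    out["significant"] = out["q_value"] < alpha
    pooled = X / N
    return CompositionResult(
        table=out, pooled_fraction=pooled, n_perm=n_perm, seed=seed, alpha=alpha
    )


def exact_enumeration_test(
    cells: pd.DataFrame, calls: GenotypeCallSet, max_cells: int = 12
) -> pd.DataFrame:
    """Exact permutation p-values by exhaustive enumeration (small instances).

    Enumerates all C(N, X) distinct assignments of the genotype multiset to
    cells; p_c is the fraction of assignments with T_c >= observed T_c.
    Refuses instances with more than ``max_cells`` cells.
    """
    tab = composition_fractions(cells, calls, min_cells=1)
    n_c, x_c, N, X, t_obs = _observed_stats(tab)
    if N > max_cells:
        raise ValueError(
            f"{N} cells exceeds the enumeration limit of {max_cells}; "
            "use permutation_test_composition instead"
        )
    merged = _join_calls(cells, calls)
    type_of_cell = merged["cell_type"].to_numpy()
    types = tab["cell_type"].to_numpy()
    type_idx = {t: i for i, t in enumerate(types)}
    cell_type_idx = np.array([type_idx[t] for t in type_of_cell])

    n_assign = comb(N, X)
    hits = np.zeros(len(types), dtype=np.int64)
    for subset in combinations(range(N), X):
        counts = np.bincount(cell_type_idx[list(subset)], minlength=len(types))
        t = np.abs(counts * N - X * n_c)
        hits += t >= t_obs
    out = tab[["cell_type", "n_cells", "n_xyyy", "fraction"]].copy()
    out["p_exact"] = hits / n_assign
    return out
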