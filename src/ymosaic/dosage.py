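"""Y/X expression-dosage ratios and comparison against reference male profiles.

The headline quantity is the pseudobulk ratio r = (sum of Y-panel UMIs) /
(sum of X-panel UMIs) over a cell group. In a lineage carrying three Y and one
X chromosome, r is expected to be about three times the ratio of a normal
XY profile, so an elevated case ratio relative to healthy-male references is
the expression-level signature of the Y gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation_io import CountMatrix, GenePanel
from .errors import EmptyResultError, YmosaicError

__all__ = ["DosageRatio", "yx_ratio", "compare_to_reference"]


class UndefinedRatioError(YmosaicError):
    """The X-panel UMI sum is zero: the Y/X ratio is undefined."""


@dataclass
class DosageRatio:
    """Pseudobulk Y/X UMI ratio for one cell group."""

    label: str
    y_sum: int
    x_sum: int
    ratio: float
    n_cells: int
    per_cell: np.ndarray | None = None  # optional (y+pc)/(x+pc) per cell, for plotting

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "y_sum": int(self.y_sum),
            "x_sum": int(self.x_sum),
            "ratio": float(self.ratio),
            "n_cells": int(self.n_cells),
        }


def yx_ratio(
    counts: CountMatrix,
    cell_mask,
    panel: GenePanel,
    label: str = "group",
    per_cell: bool = False,
    pseudocount: float = 1.0,
) -> DosageRatio:
    """Pseudobulk Y/X ratio over the masked cells.

    Summing UMIs before dividing makes the ratio robust to per-cell zeros and
    invariant to uniform library-size scaling. Per-cell ratios (with
    pseudocount) are computed only on request, for plotting.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.sum() == 0:
        raise EmptyResultError("cell mask selects no cells")
    sub = counts.subset_cells(cell_mask)
    y = sub.sum_over_genes(panel.y_genes)
    x = sub.sum_over_genes(panel.x_genes)
    y_sum, x_sum = int(y.sum()), int(x.sum())
    if x_sum == 0:
        raise UndefinedRatioError(f"group {label!r}: X-panel UMI sum is zero")
    pc = None
    if per_cell:
        pc = (y + pseudocount) / (x + pseudocount)
    return DosageRatio(
        label=label,
        y_sum=y_sum,
        x_sum=x_sum,
        ratio=y_sum / x_sum,
        n_cells=int(cell_mask.sum()),
        per_cell=pc,
    )


def compare_to_reference(case: DosageRatio, references: list[DosageRatio]) -> dict:
    """Rank a case Y/X ratio among reference donors.

    The case is flagged "elevated" when its ratio exceeds every reference
    ratio; rank 1 means the case is the highest of case+references.
    """
    if len(references) < 2:
        raise ValueError("need at least two reference donors")
    ref = np.array([r.ratio for r in references], dtype=float)
    rank = 1 + int((ref >= case.ratio).sum())
    return {
        "case_label": case.label,
        "case_ratio": float(case.ratio),
        "reference_median": float(np.median(ref)),
        "reference_min": float(ref.min()),
        "reference_max": float(ref.max()),
        "n_reference": len(references),
        "rank": rank,
        "rank_of": len(references) + 1,
        "elevated": bool(case.ratio > ref.max()),
    }
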