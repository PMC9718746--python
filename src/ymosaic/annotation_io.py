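"""Readers/writers for 10x-style count matrices and gene annotation, PAR-aware
X/Y gene panels, and per-cell QC filtering.

The in-memory orientation is always cells x genes; 10x MatrixMarket files store
genes x cells and are transposed on load. Pseudoautosomal (PAR) genes are
excluded from both sex-chromosome panels because their transcripts cannot be
assigned to the X or the Y copy.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .errors import (
    AnnotationError,
    ConfigurationError,
    EmptyResultError,
    FormatError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GenePanel",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_cell_labels",
    "read_gene_annotation",
    "default_par_regions",
    "build_gene_panel",
    "compute_qc_metrics",
    "qc_filter",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Sparse UMI count matrix, cells x genes.

    Attributes
    ----------
    barcodes : np.ndarray of str, unique cell identifiers (rows).
    genes : DataFrame with columns ``gene_id`` (unique) and ``symbol`` (cols).
    counts : scipy.sparse.csr_matrix of non-negative integers.
    """

    barcodes: np.ndarray
    genes: pd.DataFrame
    counts: sparse.csr_matrix

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if not sparse.issparse(self.counts):
            self.counts = sparse.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("barcodes are not unique")
        if self.genes["gene_id"].duplicated().any():
            raise FormatError("gene ids are not unique")
        data = self.counts.data
        if data.size:
            if (data < 0).any():
                raise FormatError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer counts")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)
        self.genes = self.genes.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_indices(self, gene_ids) -> np.ndarray:
        """Column indices of the given gene ids (order of appearance)."""
        wanted = set(gene_ids)
        mask = self.genes["gene_id"].isin(wanted).to_numpy()
        return np.flatnonzero(mask)

    def sum_over_genes(self, gene_ids) -> np.ndarray:
        """Per-cell UMI total over a gene-id set (zeros if no gene matches)."""
        idx = self.gene_indices(gene_ids)
        if idx.size == 0:
            return np.zeros(self.n_cells, dtype=np.int64)
        return np.asarray(self.counts[:, idx].sum(axis=1)).ravel().astype(np.int64)

    def subset_cells(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(self.barcodes[idx], self.genes.copy(), self.counts[idx])


@dataclass(frozen=True)
class GenePanel:
    """Non-PAR Y-linked and X-linked gene-id sets used for genotyping/dosage."""

    y_genes: frozenset = field(default_factory=frozenset)
    x_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.y_genes & self.x_genes:
            raise ConfigurationError("Y and X panels overlap")


# ---------------------------------------------------------------------------
# MatrixMarket triplet IO


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv_lines(path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_mtx_triplet(matrix_path, barcodes_path, features_path) -> CountMatrix:
    """Load a 10x-convention MTX triplet (matrix genes x cells on disk).

    Returns a :class:`CountMatrix` oriented cells x genes.
    """
    try:
        with _open_text(matrix_path) as fh:
            mat = spio.mmread(fh)
    except ValueError as exc:
        raise FormatError(f"invalid MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sparse.coo_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{matrix_path}: UMI counts must be integers")

    feature_lines = _read_tsv_lines(features_path)
    barcode_lines = _read_tsv_lines(barcodes_path)
    if mat.shape[0] != len(feature_lines):
        raise FormatError(
            f"matrix header declares {mat.shape[0]} genes but "
            f"{features_path} has {len(feature_lines)} rows"
        )
    if mat.shape[1] != len(barcode_lines):
        raise FormatError(
            f"matrix header declares {mat.shape[1]} cells but "
            f"{barcodes_path} has {len(barcode_lines)} rows"
        )

    ids, symbols = [], []
    for line in feature_lines:
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{features_path}: expected >=2 columns (id, symbol)")
        ids.append(parts[0])
        symbols.append(parts[1])
    genes = pd.DataFrame({"gene_id": ids, "symbol": symbols})
    barcodes = np.array([line.split("\t")[0] for line in barcode_lines], dtype=object)
    counts = mat.T.tocsr()
    return CountMatrix(barcodes=barcodes, genes=genes, counts=counts)


def write_mtx_triplet(cm: CountMatrix, matrix_path, barcodes_path, features_path) -> None:
    """Write a CountMatrix as a genes x cells MTX triplet (10x v3 layout)."""
    spio.mmwrite(str(matrix_path), cm.counts.T.tocoo(), field="integer")
    with open(barcodes_path, "w") as fh:
        for bc in cm.barcodes:
            fh.write(f"{bc}\n")
    with open(features_path, "w") as fh:
        for _, row in cm.genes.iterrows():
            fh.write(f"{row['gene_id']}\t{row['symbol']}\tGene Expression\n")


def read_cell_labels(path) -> pd.DataFrame:
    """Read a per-cell label table (TSV with columns barcode, cell_type)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"barcode", "cell_type"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["barcode"].duplicated().any():
        raise FormatError(f"{path}: duplicated barcodes")
    return df


# ---------------------------------------------------------------------------
# gene annotation and panels


def default_par_regions() -> list[tuple[str, int, int]]:
    """GRCh38 pseudoautosomal regions (1-based inclusive) from packaged config."""
    with resources.files("ymosaic.data").joinpath("par_grch38.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return [(str(r["chrom"]), int(r["start"]), int(r["end"])) for r in raw["par_regions"]]


def _normalize_chrom(chrom: str) -> str:
    chrom = str(chrom)
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    if chrom in ("M", "MT", "Mito"):
        return "MT"
    return chrom


def _par_flag(chrom, start, end, par_regions) -> bool:
    if chrom not in ("X", "Y"):
        return False
    for pchrom, pstart, pend in par_regions:
        if _normalize_chrom(pchrom) != chrom:
            continue
        # 1-based inclusive intervals; >=1 shared base counts as overlap
        if start is not None and end is not None and start <= pend and end >= pstart:
            return True
    return False


def read_gene_annotation(path, format: str = "tsv", par_regions=None) -> pd.DataFrame:
    """Read gene annotation and assign chromosome + PAR flag per gene.

    Parameters
    ----------
    path : GTF file (gene-level records required) or TSV with header columns
        gene_id, symbol, chromosome[, start, end].
    format : "gtf" or "tsv".
    par_regions : list of (chrom, start, end), 1-based inclusive; defaults to
        the packaged GRCh38 PAR1/PAR2 coordinates.

    Returns a DataFrame with columns gene_id, symbol, chromosome, par.
    """
    if par_regions is None:
        par_regions = default_par_regions()

    if format == "gtf":
        records = _read_gtf_genes(path)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        need = {"gene_id", "symbol", "chromosome"}
        if not need <= set(df.columns):
            raise FormatError(f"{path}: annotation TSV needs columns {sorted(need)}")
        records = []
        for _, row in df.iterrows():
            start = int(row["start"]) if "start" in df.columns and pd.notna(row.get("start")) else None
            end = int(row["end"]) if "end" in df.columns and pd.notna(row.get("end")) else None
            records.append((str(row["gene_id"]), str(row["symbol"]),
                            _normalize_chrom(row["chromosome"]), start, end))
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    out = []
    for gene_id, symbol, chrom, start, end in records:
        if chrom in ("X", "Y") and par_regions and (start is None or end is None):
            raise AnnotationError(
                f"gene {gene_id} on chromosome {chrom} lacks coordinates; "
                "cannot evaluate PAR overlap"
            )
        out.append(
            {
                "gene_id": gene_id,
                "symbol": symbol,
                "chromosome": chrom,
                "par": _par_flag(chrom, start, end, par_regions),
            }
        )
    ann = pd.DataFrame(out, columns=["gene_id", "symbol", "chromosome", "par"])
    if ann["gene_id"].duplicated().any():
        raise AnnotationError("duplicate gene ids in annotation")
    return ann


def _read_gtf_genes(path):
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("gene_id", [gene.id])[0]
        symbol = gene.attributes.get("gene_name", [gene_id])[0]
        records.append((gene_id, symbol, _normalize_chrom(gene.seqid), gene.start, gene.end))
    if not records:
        raise FormatError(f"{path}: no gene-level records found in GTF")
    return records


def build_gene_panel(annotations: pd.DataFrame) -> GenePanel:
    """Non-PAR Y and X gene-id panels from an annotation table.

    Raises :class:`ConfigurationError` when the Y panel would be empty, since
    presence/absence genotyping is then impossible.
    """
    if annotations.empty:
        raise ConfigurationError("empty annotation")
    nonpar = annotations[~annotations["par"].astype(bool)]
    y = frozenset(nonpar.loc[nonpar["chromosome"] == "Y", "gene_id"])
    x = frozenset(nonpar.loc[nonpar["chromosome"] == "X", "gene_id"])
    if not y:
        raise ConfigurationError(
            "no non-PAR Y-linked genes in annotation: genotyping impossible"
        )
    return GenePanel(y_genes=y, x_genes=x)


# ---------------------------------------------------------------------------
# QC


def compute_qc_metrics(cm: CountMatrix, mito_symbol_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics: genes detected, total UMIs, mitochondrial fraction.

    Mitochondrial genes are identified by symbol prefix (10x convention).
    """
    counts = cm.counts
    n_genes = counts.getnnz(axis=1)
    total = np.asarray(counts.sum(axis=1)).ravel()
    mito_mask = cm.genes["symbol"].astype(str).str.startswith(mito_symbol_prefix).to_numpy()
    if mito_mask.any():
        mito = np.asarray(counts[:, np.flatnonzero(mito_mask)].sum(axis=1)).ravel()
    else:
        mito = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "barcode": cm.barcodes,
            "n_genes": n_genes.astype(int),
            "total_umi": total.astype(int),
            "mito_fraction": frac,
        }
    )


def qc_filter(
    cm: CountMatrix,
    cells: pd.DataFrame | None = None,
    min_genes: int = 200,
    min_umi: int = 500,
    max_mito_fraction: float = 0.10,
    mito_symbol_prefix: str = "MT-",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove cells failing any QC threshold from matrix and cell table.

    Metrics are recomputed from the matrix so the returned table is always
    consistent with it. Order is preserved; idempotent by construction.
    """
    if min(min_genes, min_umi) < 0 or max_mito_fraction < 0:
        raise ConfigurationError("QC thresholds must be non-negative")
    metrics = compute_qc_metrics(cm, mito_symbol_prefix=mito_symbol_prefix)
    keep = (
        (metrics["n_genes"] >= min_genes)
        & (metrics["total_umi"] >= min_umi)
        & (metrics["mito_fraction"] <= max_mito_fraction)
    ).to_numpy()
    if not keep.any():
        raise EmptyResultError(
            f"all {cm.n_cells} cells removed by QC "
            f"(min_genes={min_genes}, min_umi={min_umi}, "
            f"max_mito_fraction={max_mito_fraction})"
        )
    filtered = cm.subset_cells(keep)
    out_metrics = metrics.loc[keep].reset_index(drop=True)
    if cells is not None:
        cells = cells.set_index("barcode").loc[filtered.barcodes].reset_index()
        out = cells.merge(
            out_metrics, on="barcode", how="left", suffixes=("", "_qc")
        )
    else:
        out = out_metrics
    logger.info(
        "QC kept %d/%d cells (median genes %.0f, median UMIs %.0f)",
        int(keep.sum()),
        cm.n_cells,
        float(out_metrics["n_genes"].median()),
        float(out_metrics["total_umi"].median()),
    )
    return filtered, out
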