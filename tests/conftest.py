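import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from ymosaic import CountMatrix, GenotypeCallSet
from ymosaic.genotyping import CALL_X, CALL_XYYY


def make_count_matrix(counts, gene_ids=None, symbols=None, barcodes=None) -> CountMatrix:
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    if gene_ids is None:
        gene_ids = [f"G{j}" for j in range(n_genes)]
    if symbols is None:
        symbols = list(gene_ids)
    if barcodes is None:
        barcodes = [f"BC{i}" for i in range(n_cells)]
    return CountMatrix(
        barcodes=np.array(barcodes, dtype=object),
        genes=pd.DataFrame({"gene_id": gene_ids, "symbol": symbols}),
        counts=sparse.csr_matrix(counts),
    )


def make_callset(barcodes, xyyy_flags, y_umi=None) -> GenotypeCallSet:
    xyyy_flags = np.asarray(xyyy_flags, dtype=bool)
    if y_umi is None:
        y_umi = xyyy_flags.astype(int)
    calls = pd.DataFrame(
        {
            "barcode": list(barcodes),
            "call": np.where(xyyy_flags, CALL_XYYY, CALL_X),
            "y_umi": y_umi,
        }
    )
    n_xyyy = int(xyyy_flags.sum())
    return GenotypeCallSet(
        calls=calls,
        min_y_umi=1,
        n_x=len(calls) - n_xyyy,
        n_xyyy=n_xyyy,
        f_obs=n_xyyy / len(calls),
    )


@pytest.fixture
def toy_annotation() -> pd.DataFrame:
    """Annotation with one non-PAR Y, one non-PAR X, one PAR and one autosomal gene."""
    return pd.DataFrame(
        {
            "gene_id": ["Y1", "X1", "P1", "A1"],
            "symbol": ["RPS4Y1", "XIST", "SLC25A6", "GAPDH"],
            "chromosome": ["Y", "X", "Y", "7"],
            "par": [False, False, True, False],
        }
    )


@pytest.fixture
def small_sim():
    """One small simulated mosaic sample shared across tests (seeded)."""
    from ymosaic import SimConfig, simulate_pbmc

    cfg = SimConfig(
        seed=11,
        n_cells=800,
        n_autosomal=120,
        n_x=15,
        n_y=6,
        n_par=3,
        n_mt=5,
        n_low_quality=0,
        library_median_umi=2000.0,
    )
    cm, cells, truth = simulate_pbmc(cfg)
    return cm, cells, truth
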