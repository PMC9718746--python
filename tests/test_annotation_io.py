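import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ymosaic import (
    build_gene_panel,
    qc_filter,
    read_gene_annotation,
    read_mtx_triplet,
    write_mtx_triplet,
)
from ymosaic.annotation_io import compute_qc_metrics, read_cell_labels
from ymosaic.errors import (
    AnnotationError,
    ConfigurationError,
    EmptyResultError,
    FormatError,
)

from conftest import make_count_matrix


def write_triplet_files(tmp_path, cm):
    paths = (tmp_path / "m.mtx", tmp_path / "b.tsv", tmp_path / "f.tsv")
    write_mtx_triplet(cm, *paths)
    return paths


class TestMtxTriplet:
    def test_toy_triplet_is_transposed_to_cells_by_genes(self, tmp_path):
        # genes x cells on disk: g1/c1=5, g3/c2=1
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 2 2\n1 1 5\n3 2 1\n"
        )
        (tmp_path / "b.tsv").write_text("c1\nc2\n")
        (tmp_path / "f.tsv").write_text("g1\tS1\ng2\tS2\ng3\tS3\n")
        cm = read_mtx_triplet(tmp_path / "m.mtx", tmp_path / "b.tsv", tmp_path / "f.tsv")
        assert cm.counts.shape == (2, 3)
        assert np.asarray(cm.counts.sum(axis=1)).ravel().tolist() == [5, 1]
        assert cm.counts[0, 0] == 5 and cm.counts[1, 2] == 1

    def test_empty_matrix_yields_zeros_of_declared_shape(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 2 0\n"
        )
        (tmp_path / "b.tsv").write_text("c1\nc2\n")
        (tmp_path / "f.tsv").write_text("g1\tS1\ng2\tS2\ng3\tS3\n")
        cm = read_mtx_triplet(tmp_path / "m.mtx", tmp_path / "b.tsv", tmp_path / "f.tsv")
        assert cm.counts.shape == (2, 3)
        assert cm.counts.nnz == 0

    def test_header_vs_tsv_mismatch_raises(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 2 0\n"
        )
        (tmp_path / "b.tsv").write_text("c1\nc2\nc3\n")  # one barcode too many
        (tmp_path / "f.tsv").write_text("g1\tS1\ng2\tS2\ng3\tS3\n")
        with pytest.raises(FormatError, match="cells"):
            read_mtx_triplet(tmp_path / "m.mtx", tmp_path / "b.tsv", tmp_path / "f.tsv")

    def test_non_integer_counts_raise(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n1 1 1\n1 1 2.5\n"
        )
        (tmp_path / "b.tsv").write_text("c1\n")
        (tmp_path / "f.tsv").write_text("g1\tS1\n")
        with pytest.raises(FormatError, match="integer"):
            read_mtx_triplet(tmp_path / "m.mtx", tmp_path / "b.tsv", tmp_path / "f.tsv")

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_is_count_identical(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(0.8, size=(rng.integers(1, 12), rng.integers(1, 15)))
        cm = make_count_matrix(counts)
        tmp = tmp_path_factory.mktemp(f"rt{seed}")
        cm2 = read_mtx_triplet(*write_triplet_files(tmp, cm))
        assert (cm.counts != cm2.counts).nnz == 0
        assert list(cm.barcodes) == list(cm2.barcodes)
        assert cm.genes["gene_id"].tolist() == cm2.genes["gene_id"].tolist()


class TestAnnotation:
    def test_tsv_par_flagging(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "gene_id\tsymbol\tchromosome\tstart\tend\n"
            "ENSG0001\tRPS4Y1\tY\t2841602\t2932000\n"  # outside PAR1
            "ENSG0002\tSLC25A6\tY\t1386152\t1392113\n"  # inside PAR1
            "ENSG0003\tAUTO\t7\t100\t200\n"
        )
        ann = read_gene_annotation(p, format="tsv").set_index("gene_id")
        assert ann.loc["ENSG0001", "chromosome"] == "Y" and not ann.loc["ENSG0001", "par"]
        assert bool(ann.loc["ENSG0002", "par"])
        assert ann.loc["ENSG0003", "chromosome"] == "7" and not ann.loc["ENSG0003", "par"]

    def test_single_base_overlap_counts_as_par(self, tmp_path):
        p = tmp_path / "ann.tsv"
        # ends exactly at PAR1 start base 10001
        p.write_text("gene_id\tsymbol\tchromosome\tstart\tend\nG1\tS\tY\t9000\t10001\n")
        ann = read_gene_annotation(p, format="tsv")
        assert bool(ann.loc[0, "par"])

    def test_sex_gene_without_coordinates_raises(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("gene_id\tsymbol\tchromosome\nG1\tS\tY\n")
        with pytest.raises(AnnotationError):
            read_gene_annotation(p, format="tsv")

    def test_gtf_gene_records(self, tmp_path):
        p = tmp_path / "ann.gtf"
        p.write_text(
            'chrY\thavana\tgene\t2841602\t2932000\t.\t+\t.\tgene_id "ENSG0001"; gene_name "RPS4Y1";\n'
            'chrX\thavana\tgene\t73820651\t73852753\t.\t-\t.\tgene_id "ENSG0002"; gene_name "XIST";\n'
        )
        ann = read_gene_annotation(p, format="gtf").set_index("gene_id")
        assert ann.loc["ENSG0001", "chromosome"] == "Y"
        assert ann.loc["ENSG0002", "symbol"] == "XIST"
        assert not ann["par"].any()


class TestGenePanel:
    def test_panels_follow_chromosome_and_par(self, toy_annotation):
        panel = build_gene_panel(toy_annotation)
        assert panel.y_genes == {"Y1"}
        assert panel.x_genes == {"X1"}

    def test_all_autosome_annotation_is_configuration_error(self):
        ann = pd.DataFrame(
            {"gene_id": ["A"], "symbol": ["A"], "chromosome": ["7"], "par": [False]}
        )
        with pytest.raises(ConfigurationError):
            build_gene_panel(ann)

    def test_panel_invariant_to_record_order(self, toy_annotation):
        shuffled = toy_annotation.sample(frac=1.0, random_state=5)
        assert build_gene_panel(toy_annotation) == build_gene_panel(shuffled)

    def test_panel_size_matches_independent_count(self, small_sim):
        _, _, truth = small_sim
        ann = truth.annotations
        panel = build_gene_panel(ann)
        # independent recount straight off the annotation table
        n_y = sum(
            1 for _, r in ann.iterrows() if r["chromosome"] == "Y" and not r["par"]
        )
        assert len(panel.y_genes) == n_y


class TestQcFilter:
    def test_threshold_on_genes_detected(self):
        rng = np.random.default_rng(0)
        # three cells with ~150, ~500, ~2000 genes detected
        counts = np.zeros((3, 2500), dtype=int)
        for i, k in enumerate([150, 500, 2000]):
            cols = rng.choice(2500, size=k, replace=False)
            counts[i, cols] = 1
        cm = make_count_matrix(counts)
        filtered, cells = qc_filter(cm, min_genes=200, min_umi=0, max_mito_fraction=1.0)
        assert filtered.n_cells == 2
        assert cells["n_genes"].min() >= 200

    def test_zero_thresholds_are_identity(self, small_sim):
        cm, _, _ = small_sim
        filtered, _ = qc_filter(cm, min_genes=0, min_umi=0, max_mito_fraction=1.0)
        assert filtered.n_cells == cm.n_cells

    def test_idempotence(self, small_sim):
        cm, cells, _ = small_sim
        once, cells1 = qc_filter(cm, cells, min_genes=50, min_umi=300)
        twice, cells2 = qc_filter(once, cells1[["barcode", "cell_type"]], min_genes=50, min_umi=300)
        assert list(once.barcodes) == list(twice.barcodes)

    def test_planted_low_quality_cells_are_exactly_removed(self):
        from ymosaic import SimConfig, simulate_pbmc

        cfg = SimConfig(
            seed=3, n_cells=500, n_autosomal=400, n_x=15, n_y=6, n_par=3, n_mt=5,
            n_low_quality=25, low_quality_umi=100.0,
        )
        cm, cells, truth = simulate_pbmc(cfg)
        filtered, _ = qc_filter(cm, cells, min_genes=120, min_umi=500, max_mito_fraction=1.0)
        kept = set(filtered.barcodes)
        planted = set(truth.cells.loc[truth.cells["low_quality"], "barcode"])
        assert kept == set(cm.barcodes) - planted

    def test_all_cells_removed_raises(self, small_sim):
        cm, _, _ = small_sim
        with pytest.raises(EmptyResultError):
            qc_filter(cm, min_umi=10**9)

    def test_metrics_consistent_with_matrix(self, small_sim):
        cm, _, _ = small_sim
        m = compute_qc_metrics(cm)
        assert (m["n_genes"] == cm.counts.getnnz(axis=1)).all()
        assert (m["total_umi"] == np.asarray(cm.counts.sum(axis=1)).ravel()).all()


def test_cell_label_reader_requires_columns(tmp_path):
    p = tmp_path / "labels.tsv"
    p.write_text("barcode\tkind\nb1\tB cells\n")
    with pytest.raises(FormatError):
        read_cell_labels(p)
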