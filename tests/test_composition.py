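import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ymosaic import (
    build_gene_panel,
    call_genotype,
    composition_fractions,
    exact_enumeration_test,
    permutation_test_composition,
    simulate_pbmc,
)
from ymosaic import SimConfig
from ymosaic.errors import JoinError

from conftest import make_callset


def six_cell_instance():
    """Types A (3 cells, all 45,X) and B (3 cells, all 48,XYYY)."""
    barcodes = [f"b{i}" for i in range(6)]
    cells = pd.DataFrame({"barcode": barcodes, "cell_type": ["A"] * 3 + ["B"] * 3})
    calls = make_callset(barcodes, [False] * 3 + [True] * 3)
    return cells, calls


class TestFractions:
    def test_zero_fraction_type(self):
        cells = pd.DataFrame({"barcode": ["a", "b", "c"], "cell_type": ["A"] * 3})
        calls = make_callset(["a", "b", "c"], [False, False, False])
        tab = composition_fractions(cells, calls)
        assert tab.loc[0, "fraction"] == 0.0
        assert bool(tab.loc[0, "low_n"])

    def test_single_type_equals_pooled(self):
        cells = pd.DataFrame({"barcode": list("abcd"), "cell_type": ["T"] * 4})
        calls = make_callset(list("abcd"), [True, False, True, True])
        tab = composition_fractions(cells, calls)
        assert tab.loc[0, "fraction"] == pytest.approx(0.75)

    def test_barcode_mismatch_lists_offenders(self):
        cells = pd.DataFrame({"barcode": ["a", "b"], "cell_type": ["A", "B"]})
        calls = make_callset(["a", "z"], [True, False])
        with pytest.raises(JoinError) as err:
            composition_fractions(cells, calls)
        assert set(err.value.offenders) == {"b", "z"}

    def test_per_type_fractions_near_simulated_truth(self):
        cfg = SimConfig(
            seed=8, n_cells=2000, n_autosomal=60, n_x=10, n_y=5, n_par=2, n_mt=3,
            n_low_quality=0,
            cell_types={"A": 0.5, "B": 0.5},
            lineage_fractions={"A": 0.2, "B": 0.8},
        )
        cm, cells, truth = simulate_pbmc(cfg)
        panel = build_gene_panel(truth.annotations)
        calls = call_genotype(cm, panel)
        tab = composition_fractions(cells, calls).set_index("cell_type")
        for t, f in (("A", 0.2), ("B", 0.8)):
            n = int(tab.loc[t, "n_cells"])
            ci = stats.binomtest(int(tab.loc[t, "n_xyyy"]), n, f).proportion_ci(0.999)
            assert ci.low <= f <= ci.high


class TestPermutationTest:
    def test_all_one_genotype_gives_p_one(self):
        cells = pd.DataFrame(
            {"barcode": [f"b{i}" for i in range(40)],
             "cell_type": ["A"] * 20 + ["B"] * 20}
        )
        calls = make_callset(cells["barcode"], [True] * 40)
        res = permutation_test_composition(cells, calls, n_perm=500, seed=0)
        assert (res.table["p_value"] == 1.0).all()

    def test_six_cell_instance_matches_exact_enumeration(self):
        cells, calls = six_cell_instance()
        exact = exact_enumeration_test(cells, calls).set_index("cell_type")
        assert exact.loc["A", "p_exact"] == pytest.approx(2 / 20)
        assert exact.loc["B", "p_exact"] == pytest.approx(2 / 20)
        res = permutation_test_composition(cells, calls, n_perm=10_000, seed=1)
        se = np.sqrt(0.1 * 0.9 / 10_000)
        p_mc = res.table.set_index("cell_type").loc["A", "p_value"]
        assert abs(p_mc - 0.1) <= 3 * se + 1 / 10_001

    def test_pvalues_respect_monte_carlo_floor(self):
        cells, calls = six_cell_instance()
        res = permutation_test_composition(cells, calls, n_perm=200, seed=2)
        assert (res.table["p_value"] >= 1 / 201).all()
        assert (res.table["p_value"] <= 1.0).all()

    def test_invariant_to_genotype_relabeling(self):
        cells, calls = six_cell_instance()
        flipped = make_callset(cells["barcode"], [True] * 3 + [False] * 3)
        a = permutation_test_composition(cells, calls, n_perm=3000, seed=3).table
        b = permutation_test_composition(cells, flipped, n_perm=3000, seed=3).table
        assert np.allclose(a["p_value"], b["p_value"])

    def test_too_few_permutations_refused(self):
        cells, calls = six_cell_instance()
        with pytest.raises(ValueError):
            permutation_test_composition(cells, calls, n_perm=50, seed=0)

    def test_seed_reproducibility(self):
        cells, calls = six_cell_instance()
        a = permutation_test_composition(cells, calls, n_perm=1000, seed=9).table
        b = permutation_test_composition(cells, calls, n_perm=1000, seed=9).table
        assert a.equals(b)

    def test_null_pvalues_valid_and_not_degenerate(self):
        # Global null: per-type p-values must be valid (super-uniform,
        # P(p <= t) <= t) at every level. Exact KS-uniformity is unattainable
        # here because the permutation statistic is discrete (two-sided tail
        # mass jumps by ~2x the central hypergeometric pmf), so validity plus
        # a lower bound against extreme conservatism is the testable property.
        rng = np.random.default_rng(0)
        pvals = {"A": [], "B": []}
        n_rep = 1000
        for _ in range(n_rep):
            n = 200
            barcodes = [f"b{i}" for i in range(n)]
            cells = pd.DataFrame(
                {"barcode": barcodes, "cell_type": ["A"] * 100 + ["B"] * 100}
            )
            calls = make_callset(barcodes, rng.random(n) < 0.5)
            res = permutation_test_composition(cells, calls, n_perm=1000,
                                               seed=int(rng.integers(2**31)))
            t = res.table.set_index("cell_type")
            pvals["A"].append(t.loc["A", "p_value"])
            pvals["B"].append(t.loc["B", "p_value"])
        for t in ("A", "B"):
            p = np.asarray(pvals[t])
            for level in (0.01, 0.05, 0.10, 0.25, 0.5):
                emp = (p <= level).mean()
                se = math.sqrt(level * (1 - level) / n_rep)
                assert emp <= level + 3 * se, (t, level, emp)
            # not degenerately conservative either
            assert (p <= 0.5).mean() >= 0.25

    def test_power_at_large_separation(self):
        # 0.35 vs 0.65 at 500 cells/type is essentially always detected
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            barcodes = [f"b{i}" for i in range(1000)]
            cells = pd.DataFrame(
                {"barcode": barcodes, "cell_type": ["A"] * 500 + ["B"] * 500}
            )
            flags = np.concatenate(
                [rng.random(500) < 0.35, rng.random(500) < 0.65]
            )
            calls = make_callset(barcodes, flags)
            res = permutation_test_composition(
                cells, calls, n_perm=2000, seed=int(rng.integers(2**31))
            )
            if (res.table["q_value"] < 0.05).all():
                hits += 1
        assert hits >= int(0.95 * n_rep)


class TestExactEnumeration:
    def test_two_cells_one_type_gives_p_one(self):
        cells = pd.DataFrame({"barcode": ["a", "b"], "cell_type": ["T", "T"]})
        calls = make_callset(["a", "b"], [True, False])
        tab = exact_enumeration_test(cells, calls)
        assert tab.loc[0, "p_exact"] == 1.0

    def test_refuses_large_instances(self):
        barcodes = [f"b{i}" for i in range(13)]
        cells = pd.DataFrame({"barcode": barcodes, "cell_type": ["A"] * 13})
        calls = make_callset(barcodes, [True] * 6 + [False] * 7)
        with pytest.raises(ValueError, match="enumeration limit"):
            exact_enumeration_test(cells, calls)

    def test_monte_carlo_converges_to_exact(self):
        rng = np.random.default_rng(4)
        barcodes = [f"b{i}" for i in range(10)]
        cells = pd.DataFrame(
            {"barcode": barcodes,
             "cell_type": ["A"] * 4 + ["B"] * 3 + ["C"] * 3}
        )
        calls = make_callset(barcodes, rng.random(10) < 0.5)
        exact = exact_enumeration_test(cells, calls)["p_exact"].to_numpy()
        mc = permutation_test_composition(cells, calls, n_perm=100_000, seed=5)
        p_mc = mc.table["p_value"].to_numpy()
        se = np.sqrt(exact * (1 - exact) / 100_000)
        assert np.all(np.abs(p_mc - exact) <= 4 * se + 2 / 100_001)


def test_fraction_table_preserves_totals():
    rng = np.random.default_rng(6)
    barcodes = [f"b{i}" for i in range(100)]
    cells = pd.DataFrame(
        {"barcode": barcodes, "cell_type": rng.choice(["A", "B", "C"], 100)}
    )
    calls = make_callset(barcodes, rng.random(100) < 0.4)
    tab = composition_fractions(cells, calls)
    assert tab["n_cells"].sum() == 100
    assert tab["n_xyyy"].sum() == calls.n_xyyy
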