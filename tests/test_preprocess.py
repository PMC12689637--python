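"""Filtering, normalization, DE stand-in, and the intersection rule."""
import numpy as np
import pandas as pd
import pytest

from consnet.preprocess import (consensus_degs, cpm_filter,
                                differential_expression,
                                median_of_ratios_normalize)
from consnet.synthdata import SynthConfig, generate_study, \
    plant_differential_expression

from conftest import make_counts


class TestCpmFilter:
    def test_boundary_gene_at_70_percent_retained(self):
        # 1 count in 7/10 samples with library size 1e6 -> cpm >= 1 in 70%
        x = np.ones((1, 10), dtype=int)
        x[0, 7:] = 0
        filler = np.full((1, 10), 10**6) - x  # library size exactly 1e6
        cm = make_counts(np.vstack([x, filler]))
        out = cpm_filter(cm, min_cpm=1.0, min_frac=0.7)
        assert "g0" in out.genes

    def test_all_zero_gene_removed(self):
        cm = make_counts([[0, 0, 0], [5, 6, 7]])
        out = cpm_filter(cm)
        assert out.genes == ["g1"]

    def test_matches_brute_force_oracle(self, rng):
        x = rng.integers(0, 50, size=(50, 8))
        cm = make_counts(x)
        out = cpm_filter(cm, min_cpm=1.0, min_frac=0.7)
        lib = x.sum(axis=0)
        expected = []
        for i in range(50):
            ok = sum(x[i, j] / lib[j] * 1e6 >= 1.0 for j in range(8))
            if ok / 8 >= 0.7:
                expected.append(f"g{i}")
        assert out.genes == expected

    def test_idempotent(self, rng):
        cm = make_counts(rng.integers(0, 30, size=(40, 6)))
        once = cpm_filter(cm)
        twice = cpm_filter(once)
        assert once.counts.equals(twice.counts)


class TestMedianOfRatios:
    def test_identical_columns_unit_factors(self):
        col = np.array([[3], [10], [25]])
        cm = make_counts(np.hstack([col] * 4))
        _, sf = median_of_ratios_normalize(cm)
        assert np.allclose(sf, 1.0)

    def test_doubled_column_doubles_factor(self):
        col = np.array([[3], [10], [25], [7]])
        cm = make_counts(np.hstack([col, 2 * col]))
        _, sf = median_of_ratios_normalize(cm)
        assert np.isclose(sf.iloc[1] / sf.iloc[0], 2.0)

    def test_toy_matrix_matches_hand_computation(self):
        x = np.array([[10, 20, 5, 8],
                      [100, 180, 60, 90],
                      [4, 4, 4, 4],
                      [50, 45, 55, 60],
                      [0, 3, 2, 1]])
        cm = make_counts(x)
        norm, sf = median_of_ratios_normalize(cm)
        # hand evaluation: rows with a zero are excluded from the reference
        ref = x[:4].astype(float)
        geo = np.exp(np.log(ref).mean(axis=1))
        expected_sf = np.median(ref / geo[:, None], axis=0)
        assert np.allclose(sf, expected_sf)
        assert np.allclose(norm.counts.to_numpy(), x / expected_sf[None, :])

    def test_preserves_within_sample_rank_order(self, rng):
        cm = make_counts(rng.integers(1, 100, size=(20, 5)))
        norm, _ = median_of_ratios_normalize(cm)
        for j in range(5):
            raw = cm.counts.iloc[:, j].to_numpy()
            nrm = norm.counts.iloc[:, j].to_numpy()
            assert (np.argsort(raw, kind="stable")
                    == np.argsort(nrm, kind="stable")).all()

    def test_no_common_gene_errors(self):
        cm = make_counts([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="size factors"):
            median_of_ratios_normalize(cm)


class TestDifferentialExpression:
    def test_thresholds_are_conjunctive(self):
        """Strongly significant but small-fold-change genes stay ns."""
        rng = np.random.default_rng(1)
        n = 200
        a = rng.normal(1000, 5, size=(1, n)).round().astype(int)
        b = (a * 1.1).astype(int)  # log2fc ~ 0.14 < 0.3, p tiny
        ca = make_counts(a, condition="A")
        cb = make_counts(b, condition="B")
        tab = differential_expression(ca, cb)
        row = tab.iloc[0]
        assert row.fdr < 0.05 and abs(row.log2fc) < 0.3
        assert row.direction == "ns"

    def test_planted_downshift_called_down(self):
        cfg = SynthConfig(n_genes=50, n_modules=1, module_sizes=[2],
                          n_datasets_per_condition=1, n_samples=50,
                          latent_scale=0.3, seed=9)
        mats, _, _, truth = generate_study(cfg)
        a = next(m for m in mats if m.condition == "A")
        b = next(m for m in mats if m.condition == "B")
        b = plant_differential_expression(truth, b, {"g0049": -1.0}, seed=2)
        tab = differential_expression(a, b).set_index("gene")
        assert tab.loc["g0049", "direction"] == "down"

    def test_planted_recovery_with_power_and_no_false_calls(self):
        """10 genes shifted by -0.5 log2 at n=100: recall > 0.8, no nulls called."""
        cfg = SynthConfig(n_genes=400, n_modules=1, module_sizes=[2],
                          n_datasets_per_condition=1, n_samples=100,
                          rewired_module_fraction=0.0, latent_scale=0.3,
                          seed=21)
        mats, _, _, truth = generate_study(cfg)
        a = next(m for m in mats if m.condition == "A")
        b = next(m for m in mats if m.condition == "B")
        planted = [f"g{i:04d}" for i in range(100, 110)]
        b = plant_differential_expression(
            truth, b, {g: -0.5 for g in planted}, seed=3)
        tab = differential_expression(a, b)
        called = set(tab.loc[tab.direction == "down", "gene"])
        false = set(tab.loc[tab.direction != "ns", "gene"]) - set(planted)
        assert len(called & set(planted)) / len(planted) > 0.8
        assert not false

    def test_degenerate_variance_flagged_with_p_one(self):
        ca = make_counts(np.full((2, 4), 7), condition="A")
        cb = make_counts(np.full((2, 4), 7), condition="B")
        tab = differential_expression(ca, cb)
        assert (tab.pvalue == 1.0).all()
        assert tab.degenerate.all()


def _table(sig: dict[str, str], dataset="d"):
    genes = ["g1", "g2", "g3"]
    return pd.DataFrame({
        "gene": genes,
        "log2fc": [1.0] * 3,
        "pvalue": [0.01] * 3,
        "fdr": [0.01] * 3,
        "direction": [sig.get(g, "ns") for g in genes],
        "dataset_id": dataset,
    })


class TestConsensusDegs:
    def test_consistent_in_all_tables_included(self):
        tabs = [_table({"g1": "down"}, d) for d in "abc"]
        out = consensus_degs(tabs)
        assert dict(out) == {"g1": "down"}

    def test_significant_in_two_of_three_excluded(self):
        tabs = [_table({"g1": "down"}), _table({"g1": "down"}), _table({})]
        assert consensus_degs(tabs).empty

    def test_inconsistent_direction_excluded(self):
        tabs = [_table({"g1": "up"}), _table({"g1": "down"})]
        assert consensus_degs(tabs).empty

    def test_single_table_equals_its_significant_set(self):
        t = _table({"g1": "up", "g3": "down"})
        out = consensus_degs([t])
        assert dict(out) == {"g1": "up", "g3": "down"}

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            consensus_degs([])
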