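"""Enrichment, random walk with restart, leave-one-out gate, assignment."""
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from consnet.annotate import (assign_lncrnas, cluster_enrichment,
                              loo_threshold, rwr_scores)
from consnet.containers import GeneCatalog
from consnet.topology import Partition


def solve_rwr(g: nx.Graph, seeds, r=0.7):
    """Independent oracle: direct linear solve p = r (I - (1-r)W)^-1 p0."""
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    deg = a.sum(axis=0)
    w = np.zeros_like(a)
    p0 = np.zeros(len(nodes))
    for s in seeds:
        p0[idx[s]] = 1 / len(seeds)
    for j, d in enumerate(deg):
        if d > 0:
            w[:, j] = a[:, j] / d
        else:
            w[:, j] = p0  # dangling mass teleports to the seed distribution
    p = r * np.linalg.solve(np.eye(len(nodes)) - (1 - r) * w, p0)
    return pd.Series(p, index=nodes)


def partition_of(clusters):
    cluster_of = {}
    for cid, members in clusters.items():
        for n in members:
            cluster_of[n] = cid
    return Partition(cluster_of)


class TestClusterEnrichment:
    def test_cluster_identical_to_term_hits_extreme_tail(self):
        background = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        part = partition_of({0: set(term)})
        df = cluster_enrichment(part, {"t": term}, background)
        assert df["pvalue"].iloc[0] == pytest.approx(1 / math.comb(100, 10))

    def test_toy_case_matches_enumeration_oracle(self):
        # N=50, K=10, n=10, k=5: tail sum over hypergeometric pmf
        background = {f"g{i}" for i in range(50)}
        term = {f"g{i}" for i in range(10)}
        cluster = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(20, 25)}
        df = cluster_enrichment(partition_of({0: cluster}), {"t": term},
                                background)
        expected = sum(
            math.comb(10, k) * math.comb(40, 10 - k) / math.comb(50, 10)
            for k in range(5, 11))
        assert df["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_small_terms_excluded(self):
        background = {f"g{i}" for i in range(30)}
        df = cluster_enrichment(partition_of({0: {"g0", "g1", "g2"}}),
                                {"tiny": {"g0", "g1", "g2", "g3"}}, background)
        assert df.empty

    def test_only_protein_coding_genes_tested(self):
        background = {f"g{i}" for i in range(20)}
        catalog = GeneCatalog(pd.Series(
            {f"g{i}": ("lncRNA" if i < 5 else "protein_coding")
             for i in range(20)}))
        term = {f"g{i}" for i in range(10)}
        df = cluster_enrichment(partition_of({0: set(background)}),
                                {"t": term}, background, catalog)
        # 5 lncRNAs drop out of the background, the term, and the cluster
        assert df["N"].iloc[0] == 15 and df["K"].iloc[0] == 5

    def test_null_pvalues_roughly_uniform(self):
        """With random clusters, enrichment p-values behave like a
        (conservative, discrete) null: P(p <= 0.05) stays near 0.05."""
        rng = np.random.default_rng(12)
        background = {f"g{i}" for i in range(200)}
        term = {f"g{i}" for i in rng.choice(200, 40, replace=False)}
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            cluster = {f"g{i}" for i in rng.choice(200, 50, replace=False)}
            df = cluster_enrichment(partition_of({0: cluster}), {"t": term},
                                    background)
            hits += df["pvalue"].iloc[0] <= 0.05
        assert hits / n_rep <= 0.08


class TestRwr:
    def test_two_node_closed_form(self):
        g = nx.Graph([("A", "B")])
        res = rwr_scores(g, {"A"}, r=0.7)
        assert res.scores["A"] == pytest.approx(0.7 / 0.91, abs=1e-9)
        assert res.scores["B"] == pytest.approx(0.21 / 0.91, abs=1e-9)

    def test_restart_one_returns_seed_vector(self):
        g = nx.path_graph(4)
        res = rwr_scores(g, {0, 1}, r=1.0)
        assert res.scores[0] == res.scores[1] == 0.5
        assert res.scores[2] == res.scores[3] == 0.0

    def test_symmetric_nodes_get_equal_scores(self):
        g = nx.path_graph(5)  # 0-1-2-3-4, symmetric around 2
        res = rwr_scores(g, {2}, r=0.7)
        assert res.scores[0] == pytest.approx(res.scores[4], abs=1e-9)
        assert res.scores[1] == pytest.approx(res.scores[3], abs=1e-9)

    def test_scores_sum_to_one(self):
        g = nx.gnp_random_graph(25, 0.2, seed=1)
        res = rwr_scores(g, {0, 3, 7}, r=0.7, tol=1e-12)
        assert res.scores.sum() == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_power_iteration_matches_direct_solve(self, seed):
        g = nx.gnp_random_graph(40, 0.1, seed=seed)
        seeds = {0, 1, 2}
        res = rwr_scores(g, seeds, r=0.7, tol=1e-13)
        expected = solve_rwr(g, seeds)
        assert np.abs(res.scores - expected).max() < 1e-8

    def test_seed_neighbor_outscores_distant_node(self):
        g = nx.path_graph(6)
        res = rwr_scores(g, {0}, r=0.7)
        assert res.scores[1] > res.scores[2] > res.scores[3]

    def test_empty_seeds_error(self):
        with pytest.raises(ValueError):
            rwr_scores(nx.path_graph(3), set())

    def test_seed_outside_graph_errors(self):
        with pytest.raises(ValueError):
            rwr_scores(nx.path_graph(3), {99})


class TestLooThreshold:
    def test_two_seed_path_reuses_closed_form(self):
        g = nx.Graph([("A", "B")])
        loo = loo_threshold(g, {"A", "B"}, r=0.7)
        # leaving either node out seeds the other: held-out score 0.21/0.91
        assert loo == pytest.approx(0.21 / 0.91, abs=1e-9)

    def test_disconnected_category_gene_drags_minimum_to_zero(self):
        g = nx.Graph([("A", "B")])
        g.add_node("C")
        loo = loo_threshold(g, {"A", "B", "C"}, r=0.7)
        assert loo == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_over_leave_outs(self):
        g = nx.gnp_random_graph(12, 0.4, seed=6)
        category = {0, 2, 5, 7, 9}
        loo = loo_threshold(g, category, r=0.7, tol=1e-13)
        expected = min(
            solve_rwr(g, category - {h})[h] for h in category)
        assert loo == pytest.approx(expected, abs=1e-8)

    def test_singleton_category_errors(self):
        with pytest.raises(ValueError):
            loo_threshold(nx.path_graph(3), {0})


class TestAssignLncrnas:
    def _scores(self, values):
        g = nx.complete_graph(len(values))
        res = rwr_scores(g, {0}, r=0.7)
        res.scores = pd.Series(values, index=sorted(values))
        res.nodes = sorted(values)
        return res

    def test_top_decile_eligible_with_ties(self):
        values = {f"l{i:03d}": i / 100 for i in range(100)}
        res = self._scores(values)
        tab = assign_lncrnas(res, set(values), loo_min=0.0, percentile=90)
        assert int(tab.eligible.sum()) == 10
        assert set(tab.loc[tab.eligible, "lncrna"]) == \
            {f"l{i:03d}" for i in range(90, 100)}

    def test_eligible_below_loo_floor_rejected(self):
        values = {"l1": 0.9, "l2": 0.5, "l3": 0.1}
        tab = assign_lncrnas(self._scores(values), set(values),
                             loo_min=0.95, percentile=50)
        assert not tab.accepted.any()
        assert tab.eligible.any()

    def test_no_lncrnas_gives_empty_table(self):
        values = {"l1": 0.9}
        tab = assign_lncrnas(self._scores(values), set(), loo_min=0.0)
        assert tab.empty

    def test_planted_categories_recovered_on_synthetic_study(self, default_result):
        """Accepted lncRNA assignments hit their planted category far above
        chance (all-or-near-all correct on the default study)."""
        truth = default_result.truth
        for cond in ("A", "B"):
            acc = default_result.assignments[cond]
            acc = acc.loc[acc.accepted]
            assert len(acc) > 0
            correct = sum(
                row.category in truth.lncrna_category_of.get(row.lncrna, set())
                for row in acc.itertuples())
            assert correct / len(acc) > 0.9
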