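"""Cluster enrichment and RWR-based lncRNA functional assignment.

Enrichment is one-sided hypergeometric over-representation of each category
gene set within each cluster's protein-coding genes, against a fixed
background (the protein-coding genes that entered network construction),
BH-corrected across terms within a cluster; terms with fewer than five
background genes are excluded.

Random walk with restart (RWR) scores proximity to a seed set on the
*unweighted* cluster subgraph (signed weights cannot drive a random walk):
the walker follows the column-normalized binary adjacency W and restarts at
the seeds with probability r = 0.7 each step,

    p <- (1 - r) W p + r p0,      p0 uniform over seeds,

iterated to an L1 fixed point. For each enriched category, lncRNAs in the
cluster are ranked by RWR score with the category's protein-coding genes as
seeds; those in the top decile are assigned, and an assignment is accepted
only if the score is not below the lowest leave-one-out score of the
category's own members (each member scored with the rest as seeds).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneCatalog
from .topology import Partition, to_graph

__all__ = ["cluster_enrichment", "rwr_scores", "loo_threshold",
           "assign_lncrnas", "annotate_lncrnas", "RwrResult"]

log = logging.getLogger(__name__)


def cluster_enrichment(partition: Partition, category_sets: dict[str, set[str]],
                       background: set[str], catalog: GeneCatalog | None = None,
                       min_term_size: int = 5,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation per (cluster, term).

    Only protein-coding genes are tested when a catalog is supplied. Returns
    columns cluster, term, k, K, n, N, pvalue, fdr, significant; BH is
    applied across terms within each cluster.
    """
    pc = catalog.protein_coding if catalog is not None else None
    bg = set(background) if pc is None else set(background) & pc
    N = len(bg)
    rows = []
    terms = {t: s & bg for t, s in category_sets.items()}
    terms = {t: s for t, s in terms.items() if len(s) >= min_term_size}
    for cluster, members in sorted(partition.clusters.items()):
        tested = members & bg
        n = len(tested)
        if n == 0:
            continue
        for term in sorted(terms):
            K = len(terms[term])
            k = len(tested & terms[term])
            # P(X >= k) for X ~ Hypergeom(N, K, n)
            p = stats.hypergeom.sf(k - 1, N, K, n)
            rows.append((cluster, term, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["cluster", "term", "k", "K", "n", "N",
                                     "pvalue"])
    if df.empty:
        df["fdr"] = df["significant"] = []
        return df
    df["fdr"] = np.nan
    for cluster, idx in df.groupby("cluster").groups.items():
        df.loc[idx, "fdr"] = multipletests(df.loc[idx, "pvalue"],
                                           method="fdr_bh")[1]
    df["significant"] = df["fdr"] < alpha
    return df


@dataclass
class RwrResult:
    nodes: list[str]
    scores: pd.Series          # steady-state visiting probabilities
    seeds: set[str]
    restart: float
    residual: float
    n_iter: int


def rwr_scores(subgraph, seeds: set[str], r: float = 0.7,
               tol: float = 1e-10, max_iter: int = 100_000) -> RwrResult:
    """Random walk with restart on the unweighted (sub)graph.

    W is the column-normalized binary adjacency; probability mass sitting
    on degree-zero nodes teleports fully back to the seed distribution,
    keeping the iteration stochastic.
    """
    g = to_graph(subgraph)
    nodes = sorted(g.nodes)
    if not seeds:
        raise ValueError("empty seed set")
    if not set(seeds) <= set(nodes):
        raise ValueError("seeds must be nodes of the subgraph")
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    deg = a.sum(axis=0)
    dangling = deg == 0
    w = np.divide(a, deg[None, :], out=np.zeros_like(a), where=~dangling[None, :])

    p0 = np.zeros(n)
    for s in seeds:
        p0[idx[s]] = 1.0 / len(seeds)
    p = p0.copy()
    if r >= 1.0:
        return RwrResult(nodes, pd.Series(p0, index=nodes), set(seeds), r, 0.0, 0)
    for it in range(1, max_iter + 1):
        lost = p[dangling].sum()
        p_next = (1.0 - r) * (w @ p + lost * p0) + r * p0
        residual = np.abs(p_next - p).sum()
        p = p_next
        if residual < tol:
            return RwrResult(nodes, pd.Series(p, index=nodes), set(seeds),
                             r, residual, it)
    raise RuntimeError(f"RWR did not converge in {max_iter} iterations "
                       f"(residual {residual:.3g})")


def loo_threshold(subgraph, category_genes: set[str], r: float = 0.7,
                  tol: float = 1e-10) -> float:
    """Minimum leave-one-out RWR score over a category's own members."""
    genes = sorted(category_genes)
    if len(genes) < 2:
        raise ValueError("leave-one-out needs >= 2 category genes")
    lo = np.inf
    for g in genes:
        res = rwr_scores(subgraph, set(genes) - {g}, r=r, tol=tol)
        lo = min(lo, res.scores.get(g, 0.0))
    return float(lo)


def assign_lncrnas(scores: RwrResult, lncrnas: set[str], loo_min: float,
                   percentile: float = 90.0) -> pd.DataFrame:
    """Rank cluster lncRNAs by RWR score and apply the two acceptance gates.

    Eligible = score at or above the ``percentile``-th percentile of the
    cluster's lncRNA scores (ties at the threshold included); accepted =
    eligible and score >= ``loo_min``. Returns columns lncrna, score,
    percentile_rank, loo_min, eligible, accepted.
    """
    lnc = sorted(set(lncrnas) & set(scores.nodes))
    if not lnc:
        return pd.DataFrame(columns=["lncrna", "score", "percentile_rank",
                                     "loo_min", "eligible", "accepted"])
    s = scores.scores.loc[lnc].to_numpy(dtype=float)
    threshold = np.percentile(s, percentile)
    ranks = stats.rankdata(s, method="average") / len(s) * 100.0
    eligible = s >= threshold
    accepted = eligible & (s >= loo_min)
    return pd.DataFrame({
        "lncrna": lnc, "score": s, "percentile_rank": ranks,
        "loo_min": loo_min, "eligible": eligible, "accepted": accepted,
    })


def annotate_lncrnas(net, partition: Partition, catalog: GeneCatalog,
                     category_sets: dict[str, set[str]], background: set[str],
                     r: float = 0.7, percentile: float = 90.0,
                     tol: float = 1e-10, alpha: float = 0.05,
                     min_term_size: int = 5):
    """Full per-cluster workflow: enrichment, RWR, LOO gate, assignment.

    For each cluster, only that cluster's significantly enriched categories
    are tested; seeds are the category's protein-coding genes inside the
    cluster. Returns ``(enrichment table, assignment table)`` where the
    assignment table has one row per (lncrna, cluster, category).
    """
    g = to_graph(net)
    enrich = cluster_enrichment(partition, category_sets, background, catalog,
                                min_term_size=min_term_size, alpha=alpha)
    lnc_all = catalog.lncrna
    rows = []
    for cluster, members in sorted(partition.clusters.items()):
        sub = g.subgraph(members)
        lnc = set(members) & lnc_all
        sig_terms = enrich.loc[(enrich["cluster"] == cluster)
                               & enrich["significant"], "term"]
        for term in sig_terms:
            seeds = category_sets[term] & members & catalog.protein_coding
            if len(seeds) < 2 or not lnc:
                continue
            res = rwr_scores(sub, seeds, r=r, tol=tol)
            loo = loo_threshold(sub, seeds, r=r, tol=tol)
            tab = assign_lncrnas(res, lnc, loo, percentile)
            tab.insert(1, "cluster", cluster)
            tab.insert(2, "category", term)
            rows.append(tab)
    assign = (pd.concat(rows, ignore_index=True) if rows else
              pd.DataFrame(columns=["lncrna", "cluster", "category", "score",
                                    "percentile_rank", "loo_min", "eligible",
                                    "accepted"]))
    return enrich, assign
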