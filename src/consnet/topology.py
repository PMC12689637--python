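"""Network topology: k-core hub detection and Louvain clustering.

Hubs are the innermost k-core shell: coreness is computed by iterative
peeling (a node's coreness is the largest k such that it survives in the
subgraph where every node has degree >= k) and the nodes at maximum
coreness are the core hub genes. Clustering is Louvain modularity
maximization on the *unweighted* graph (signed weights cannot enter the
modularity objective), resolution 1, with clusters holding fewer than 20
intra-cluster links discarded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .containers import ConsensusNetwork, WtoNetwork

__all__ = ["to_graph", "kcore_decomposition", "louvain_clusters",
           "core_overlap", "CorenessMap", "Partition"]

log = logging.getLogger(__name__)


def to_graph(net) -> nx.Graph:
    """Simple undirected graph from a network's edge table (weights kept as attrs)."""
    if isinstance(net, ConsensusNetwork):
        edges = net.edges[["node1", "node2", "omega"]].to_numpy(dtype=object)
    elif isinstance(net, WtoNetwork):
        edges = net.edges[["node1", "node2", "wto"]].to_numpy(dtype=object)
    elif isinstance(net, nx.Graph):
        return net
    else:
        raise TypeError("expected WtoNetwork, ConsensusNetwork or nx.Graph")
    g = nx.Graph()
    g.add_weighted_edges_from(edges, weight="weight")
    return g


@dataclass
class CorenessMap:
    coreness: dict[str, int]

    @property
    def core_set(self) -> set[str]:
        if not self.coreness:
            return set()
        kmax = max(self.coreness.values())
        return {n for n, k in self.coreness.items() if k == kmax}

    def to_frame(self) -> pd.DataFrame:
        core = self.core_set
        return pd.DataFrame({
            "node": sorted(self.coreness),
            "coreness": [self.coreness[n] for n in sorted(self.coreness)],
            "is_core": [n in core for n in sorted(self.coreness)],
        })


@dataclass
class Partition:
    cluster_of: dict[str, int]
    intra_links: dict[int, int] = field(default_factory=dict)
    resolution: float = 1.0

    @property
    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for n, c in self.cluster_of.items():
            out.setdefault(c, set()).add(n)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": list(self.cluster_of),
            "cluster": list(self.cluster_of.values()),
        }).sort_values("node", kind="mergesort").reset_index(drop=True)


def kcore_decomposition(net) -> CorenessMap:
    """Coreness per node; weights are ignored, empty graphs give an empty map."""
    g = to_graph(net)
    if g.number_of_nodes() == 0:
        return CorenessMap({})
    return CorenessMap(nx.core_number(g))


def louvain_clusters(net, resolution: float = 1.0, min_links: int = 20,
                     seed: int = 0) -> Partition:
    """Louvain communities on the unweighted graph, small clusters dropped.

    Clusters with fewer than ``min_links`` intra-cluster edges are excluded
    from the partition (their nodes are simply absent from ``cluster_of``).
    Deterministic for a fixed seed; cluster ids are assigned by decreasing
    cluster size.
    """
    g = to_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    comms = nx.community.louvain_communities(
        g, weight=None, resolution=resolution, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    cluster_of: dict[str, int] = {}
    intra: dict[int, int] = {}
    cid = 0
    for comm in comms:
        n_links = g.subgraph(comm).number_of_edges()
        if n_links < min_links:
            log.info("dropping cluster with %d nodes, %d links (< %d)",
                     len(comm), n_links, min_links)
            continue
        for n in comm:
            cluster_of[n] = cid
        intra[cid] = n_links
        cid += 1
    return Partition(cluster_of, intra, resolution)


def core_overlap(core_a: CorenessMap, core_b: CorenessMap):
    """(shared, A-only, B-only) node sets of the two innermost shells."""
    a, b = core_a.core_set, core_b.core_set
    return a & b, a - b, b - a
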