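"""Signed weighted topological overlap (wTO) networks.

The adjacency is the full signed Pearson correlation matrix A = [a_ij].
The signed weighted topological overlap between genes i and j is

    w_ij = ( sum_{u != i,j} a_iu * a_uj  +  a_ij )
           / ( min(k_i, k_j) + 1 - |a_ij| ),      k_i = sum_{u != i} |a_iu|

so the direct correlation is reinforced (or cancelled) by the agreement of
the two genes' correlations to shared neighbors, and the sign is retained.
|w_ij| <= 1 whenever |a| <= 1. Weak links (|w| below a hard cutoff, default
0.5, boundary retained) are then discarded along with nodes left isolated.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, WtoNetwork

__all__ = ["pearson_adjacency", "signed_wto", "hard_threshold", "wto_from_counts"]

log = logging.getLogger(__name__)

# dense n x n float64 matrices; guard against accidental genome-scale input
MAX_GENES = 6000


@dataclass
class CorrelationMatrix:
    a: np.ndarray          # symmetric, unit diagonal
    genes: list[str]


def pearson_adjacency(cm: CountMatrix, log_transform: bool = True) -> CorrelationMatrix:
    """Signed Pearson correlation of all gene pairs.

    Correlations are computed on log2(normalized + 1) by default. Genes
    with zero variance are dropped with a warning (their correlation is
    undefined).
    """
    if len(cm.samples) < 3:
        raise ValueError("need >= 3 samples for correlation")
    if len(cm.genes) > MAX_GENES:
        raise ValueError(f"{len(cm.genes)} genes exceeds the dense-matrix cap "
                         f"of {MAX_GENES}; pre-filter the matrix")
    x = cm.counts.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    var = x.var(axis=1)
    keep = var > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes")
        x = x[keep]
    genes = [g for g, k in zip(cm.genes, keep) if k]
    a = np.corrcoef(x)
    a = np.clip((a + a.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(a, 1.0)
    return CorrelationMatrix(a, genes)


def signed_wto(corr: CorrelationMatrix) -> WtoNetwork:
    """Signed wTO for every unordered gene pair (dense matrix form).

    For i != j the numerator sum over shared neighbors equals
    (A @ A)_ij - 2 a_ij on a unit-diagonal matrix, so adding back the direct
    term gives (A @ A)_ij - a_ij.
    """
    a = corr.a
    n = a.shape[0]
    k = np.abs(a).sum(axis=1) - 1.0               # excludes the unit diagonal
    numer = a @ a - a                              # + a_ij direct term folded in
    denom = np.minimum.outer(k, k) + 1.0 - np.abs(a)
    w = numer / denom
    iu = np.triu_indices(n, k=1)
    genes = np.asarray(corr.genes, dtype=object)
    edges = pd.DataFrame({
        "node1": genes[iu[0]], "node2": genes[iu[1]],
        "wto": np.clip(w[iu], -1.0, 1.0),
    })
    return WtoNetwork(edges, nodes=list(corr.genes))


def hard_threshold(net: WtoNetwork, cutoff: float = 0.5) -> WtoNetwork:
    """Keep edges with |w| >= cutoff and only nodes incident to one.

    Logs the before/after edge and node counts (network-size bookkeeping).
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    kept = net.edges.loc[net.edges["wto"].abs() >= cutoff].reset_index(drop=True)
    surviving = sorted(set(kept["node1"]) | set(kept["node2"]))
    log.info("hard_threshold |w|>=%.3g: edges %d -> %d, nodes %d -> %d",
             cutoff, net.n_edges, len(kept), len(net.nodes), len(surviving))
    return WtoNetwork(kept, nodes=surviving)


def wto_from_counts(cm: CountMatrix, cutoff: float = 0.5,
                    log_transform: bool = True) -> WtoNetwork:
    """Convenience: correlation -> signed wTO -> hard threshold."""
    return hard_threshold(signed_wto(pearson_adjacency(cm, log_transform)), cutoff)
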