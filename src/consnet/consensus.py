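"""Consensus integration of same-region signed networks.

The consensus keeps only links present in *every* input network with a
common sign (links with differing signs are excluded) and weights each
surviving link by the magnitude-weighted average

    Omega_ij = sum_k alpha_ij^k w_ij^k,   alpha_ij^k = |w_ij^k| / sum_k |w_ij^k|

so stronger inputs contribute more: the result is a convex combination of
the inputs, bounded by their extremes, and |Omega| >= |simple mean| for
same-sign inputs.
"""
from __future__ import annotations

import logging
from functools import reduce

import numpy as np
import pandas as pd

from .containers import ConsensusNetwork, WtoNetwork

__all__ = ["integrate", "consensus_weight"]

log = logging.getLogger(__name__)


def consensus_weight(weights) -> float:
    """Magnitude-weighted average of same-sign weights (scalar form)."""
    w = np.asarray(weights, dtype=float)
    denom = np.abs(w).sum()
    if denom == 0:
        raise ValueError("all-zero weights have no defined consensus")
    return float((w * np.abs(w)).sum() / denom)


def integrate(nets: list[WtoNetwork],
              input_ids: list[str] | None = None) -> ConsensusNetwork:
    """Intersect k >= 2 signed networks and compute consensus weights.

    Edges must be present in every input; sign-discordant edges are dropped.
    Zero-weight edges (possible only if the upstream cutoff was disabled)
    are sign-neutral and excluded.
    """
    if len(nets) < 2:
        raise ValueError("consensus integration needs >= 2 networks")
    if input_ids is None:
        input_ids = [f"net{k}" for k in range(len(nets))]
    if len(input_ids) != len(nets):
        raise ValueError("input_ids length mismatch")

    tables = [
        net.edges.rename(columns={"wto": f"wto_{kid}"})
        for net, kid in zip(nets, input_ids)
    ]
    merged = reduce(
        lambda l, r: l.merge(r, on=["node1", "node2"], how="inner"), tables)
    wcols = [f"wto_{kid}" for kid in input_ids]
    w = merged[wcols].to_numpy(dtype=float)

    nonzero = (w != 0).all(axis=1)
    same_sign = (np.sign(w).max(axis=1) == np.sign(w).min(axis=1))
    keep = nonzero & same_sign
    w = w[keep]
    merged = merged.loc[keep].reset_index(drop=True)

    absw = np.abs(w)
    merged.insert(2, "omega", (w * absw).sum(axis=1) / absw.sum(axis=1))
    log.info("consensus of %d networks: %d sign-consistent common edges",
             len(nets), len(merged))
    return ConsensusNetwork(merged, input_ids=list(input_ids))
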