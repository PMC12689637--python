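"""Differential co-expression link classification between two conditions.

Every link in the union of the two networks is classified from the
definitions directly: a link is *present* in a network when |w| >= cutoff
(default 0.33, boundary inclusive); present in both with the same sign ->
``conserved``; present in both with opposite signs -> ``reversed``; present
in exactly one -> ``specific_A`` / ``specific_B``. Genes absent from one
network are added to it with zero-weight links (so a gene that dropped out
of one condition's consensus still contributes condition-specific links
rather than disappearing from the comparison); a pair below the cutoff in
both networks after augmentation is ``none``.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ConsensusNetwork, WtoNetwork

__all__ = ["classify_links", "category_abundance", "category_counts"]

CATEGORIES = ["conserved", "specific_A", "specific_B", "reversed", "none"]


def _edge_table(net) -> pd.DataFrame:
    if isinstance(net, ConsensusNetwork):
        return net.edges[["node1", "node2", "omega"]].copy()
    if isinstance(net, WtoNetwork):
        return net.edges.rename(columns={"wto": "omega"})[
            ["node1", "node2", "omega"]].copy()
    raise TypeError("expected WtoNetwork or ConsensusNetwork")


def classify_links(net_a, net_b, cutoff: float = 0.33) -> pd.DataFrame:
    """Label the union link set of two networks.

    Returns a table ``node1, node2, omega_A, omega_B, category`` where
    absent links carry weight 0 (the zero-weight augmentation).
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    ta = _edge_table(net_a).rename(columns={"omega": "omega_A"})
    tb = _edge_table(net_b).rename(columns={"omega": "omega_B"})
    merged = ta.merge(tb, on=["node1", "node2"], how="outer")
    merged[["omega_A", "omega_B"]] = merged[["omega_A", "omega_B"]].fillna(0.0)

    wa = merged["omega_A"].to_numpy()
    wb = merged["omega_B"].to_numpy()
    pa = np.abs(wa) >= cutoff
    pb = np.abs(wb) >= cutoff
    same = np.sign(wa) == np.sign(wb)
    category = np.select(
        [pa & pb & same, pa & pb & ~same, pa & ~pb, pb & ~pa],
        ["conserved", "reversed", "specific_A", "specific_B"],
        default="none")
    merged["category"] = category
    return merged.sort_values(["node1", "node2"],
                              kind="mergesort").reset_index(drop=True)


def category_counts(table: pd.DataFrame) -> pd.Series:
    """Link counts per category (all five categories, zeros included)."""
    return table["category"].value_counts().reindex(CATEGORIES, fill_value=0)


def category_abundance(table: pd.DataFrame,
                       grouping: dict[str, object]) -> pd.DataFrame:
    """Relative abundance of link categories per node group.

    A link counts toward a group only when both endpoints belong to it;
    fractions within each group sum to 1. Groups without internal links are
    omitted with a warning.
    """
    g1 = table["node1"].map(grouping)
    g2 = table["node2"].map(grouping)
    internal = table.loc[(g1 == g2) & g1.notna()].copy()
    internal["group"] = g1[internal.index]
    rows = {}
    for grp, sub in internal.groupby("group"):
        counts = category_counts(sub)
        rows[grp] = counts / counts.sum()
    wanted = set(v for v in grouping.values() if v is not None)
    for grp in wanted - set(rows):
        warnings.warn(f"group {grp!r} has no internal links; omitted")
    return pd.DataFrame(rows).T.rename_axis("group")
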