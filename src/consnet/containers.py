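"""Core in-memory containers shared across pipeline stages.

Gene identifiers are opaque strings throughout; no assumptions about
Ensembl versioning or annotation releases are made.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "GeneCatalog", "WtoNetwork", "ConsensusNetwork"]


@dataclass
class CountMatrix:
    """Gene-level counts for one dataset in one condition.

    Parameters
    ----------
    counts : pd.DataFrame
        Non-negative integer (or normalized float) values, rows indexed by
        gene id, columns by sample id. Row and column labels must be unique.
    dataset_id : str
        Identifier of the contributing dataset (e.g. a study/brain-bank code).
    condition : str
        Condition label, conventionally ``"A"`` (control) or ``"B"`` (case).
    region : str
        Tissue/region label; networks are only ever integrated within region.
    """

    counts: pd.DataFrame
    dataset_id: str = "dataset"
    condition: str = "A"
    region: str = "region"

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if (np.asarray(self.counts.values) < 0).any():
            raise ValueError("negative counts")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.dataset_id,
                           self.condition, self.region)


@dataclass
class GeneCatalog:
    """Mapping gene id -> biotype (``protein_coding`` or ``lncRNA``)."""

    biotype: pd.Series  # index gene_id, values biotype strings

    def __post_init__(self) -> None:
        if self.biotype.index.has_duplicates:
            raise ValueError("duplicate gene ids in catalog")

    @property
    def protein_coding(self) -> set[str]:
        return set(self.biotype.index[self.biotype == "protein_coding"])

    @property
    def lncrna(self) -> set[str]:
        return set(self.biotype.index[self.biotype == "lncRNA"])


def canonical_edges(df: pd.DataFrame) -> pd.DataFrame:
    """Return an edge table with node1 < node2 lexicographically, sorted."""
    df = df.copy()
    swap = df["node1"] > df["node2"]
    df.loc[swap, ["node1", "node2"]] = df.loc[swap, ["node2", "node1"]].values
    df = df.sort_values(["node1", "node2"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(["node1", "node2"]).any():
        raise ValueError("duplicate edges after canonicalization")
    return df


@dataclass
class WtoNetwork:
    """Undirected signed network: edge table (node1, node2, wto).

    Edge pairs are canonical (node1 < node2). ``nodes`` may exceed the set of
    nodes incident to an edge (e.g. before hard thresholding).
    """

    edges: pd.DataFrame
    nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"node1", "node2", "wto"}
        if not required.issubset(self.edges.columns):
            raise ValueError(f"edge table must have columns {sorted(required)}")
        self.edges = canonical_edges(self.edges[["node1", "node2", "wto"]])
        if (self.edges["node1"] == self.edges["node2"]).any():
            raise ValueError("self-loops are not allowed")
        if (self.edges["wto"].abs() > 1 + 1e-9).any():
            raise ValueError("|wto| must be <= 1")
        if not self.nodes:
            self.nodes = sorted(set(self.edges["node1"]) | set(self.edges["node2"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {(a, b): w for a, b, w in
                self.edges[["node1", "node2", "wto"]].itertuples(index=False)}


@dataclass
class ConsensusNetwork:
    """Sign-consistent intersection of k signed networks.

    ``edges`` carries the consensus weight ``omega`` plus one ``wto_<id>``
    column per input network; every retained edge was present in all inputs
    with a common sign and ``omega`` is the |w|-weighted average, so it is
    bounded by the input extremes.
    """

    edges: pd.DataFrame  # node1, node2, omega, wto_<k>...
    input_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not {"node1", "node2", "omega"}.issubset(self.edges.columns):
            raise ValueError("consensus edge table needs node1, node2, omega")
        self.edges = self.edges.sort_values(["node1", "node2"],
                                            kind="mergesort").reset_index(drop=True)

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.edges["node1"]) | set(self.edges["node2"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def as_wto_network(self) -> WtoNetwork:
        e = self.edges[["node1", "node2", "omega"]].rename(columns={"omega": "wto"})
        return WtoNetwork(e)
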