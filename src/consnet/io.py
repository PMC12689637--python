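"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV; lines starting with ``#`` are provenance/comment headers.
Edge lists are written in canonical order (node1 < node2 lexicographically)
and validated on read. Category gene sets use the GMT convention:
``term<TAB>description<TAB>gene1<TAB>gene2...``.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

from .containers import CountMatrix, GeneCatalog, WtoNetwork, canonical_edges

log = logging.getLogger(__name__)


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def write_counts(cm: CountMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# dataset={cm.dataset_id} condition={cm.condition} "
                 f"region={cm.region}\n")
        cm.counts.to_csv(fh, sep="\t", index_label="gene_id")


def read_counts(path, dataset_id=None, condition=None, region=None) -> CountMatrix:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    df = _read_tsv(path, index_col="gene_id")
    return CountMatrix(
        df,
        dataset_id=dataset_id or meta.get("dataset", "dataset"),
        condition=condition or meta.get("condition", "A"),
        region=region or meta.get("region", "region"),
    )


def write_catalog(catalog: GeneCatalog, path) -> None:
    df = catalog.biotype.rename("biotype").rename_axis("gene_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path) -> GeneCatalog:
    df = _read_tsv(path)
    if not {"gene_id", "biotype"}.issubset(df.columns):
        raise ValueError(f"{path}: catalog needs columns gene_id, biotype")
    return GeneCatalog(df.set_index("gene_id")["biotype"])


def write_gmt(category_sets: dict[str, set[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in sorted(category_sets):
            genes = sorted(category_sets[term])
            desc = descriptions.get(term, "na")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line "
                                 "(need term, description, >=1 gene)")
            term, genes = parts[0], parts[2:]
            if len(genes) != len(set(genes)):
                warnings.warn(f"{path}:{lineno}: duplicate genes in term "
                              f"{term!r}; deduplicated")
            sets[term] = set(genes)
    return sets


def write_edges(net: WtoNetwork, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        net.edges.to_csv(fh, sep="\t", index=False)


def read_edges(path) -> WtoNetwork:
    df = _read_tsv(path)
    if not {"node1", "node2", "wto"}.issubset(df.columns):
        raise ValueError(f"{path}: edge list needs columns node1, node2, wto")
    bad = df["node1"] >= df["node2"]
    if bad.any():
        # canonicalize (B, A) -> (A, B); reject self-loops outright
        if (df["node1"] == df["node2"]).any():
            raise ValueError(f"{path}: self-loop in edge list")
        df = canonical_edges(df)
    return WtoNetwork(df)


def write_table(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)
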