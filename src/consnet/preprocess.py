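"""Count filtering, normalization, and the cross-dataset DEG intersection.

The expression filter keeps genes with at least ``min_cpm`` counts per
million in at least ``min_frac`` of samples (boundary inclusive on both).
Normalization is the standard median-of-ratios size-factor estimator:
per-sample factors are the median, over genes expressed in every sample, of
the ratio of the count to the gene's geometric mean.

The per-dataset differential-expression test is a deliberately simple
deterministic engine — Welch's t-test on log2(normalized + 1) with
Benjamini-Hochberg correction — because the pipeline's own contribution is
the *intersection rule*: a gene is a consensus DEG only when significant
with a consistent direction in every contributing dataset.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

__all__ = ["cpm_filter", "median_of_ratios_normalize",
           "differential_expression", "consensus_degs"]


def cpm_filter(cm: CountMatrix, min_cpm: float = 1.0,
               min_frac: float = 0.7) -> CountMatrix:
    """Drop genes below ``min_cpm`` counts-per-million in < ``min_frac`` of samples."""
    lib = cm.counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm = cm.counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    frac_ok = (cpm >= min_cpm).mean(axis=1)
    keep = frac_ok >= min_frac
    if not keep.any():
        warnings.warn("cpm_filter removed every gene")
    return CountMatrix(cm.counts.loc[keep], cm.dataset_id, cm.condition, cm.region)


def median_of_ratios_normalize(cm: CountMatrix):
    """Median-of-ratios normalization.

    Returns ``(normalized CountMatrix, size_factors Series)``. Only genes
    with a nonzero count in every sample contribute to the per-sample
    median ratio.
    """
    x = cm.counts.to_numpy(dtype=float)
    all_expressed = (x > 0).all(axis=1)
    if not all_expressed.any():
        raise ValueError(
            f"no gene expressed in all samples of dataset {cm.dataset_id} "
            f"({cm.condition}); cannot compute size factors")
    ref = x[all_expressed]
    geomean = np.exp(np.log(ref).mean(axis=1))
    sf = np.median(ref / geomean[:, None], axis=0)
    norm = pd.DataFrame(x / sf[None, :], index=cm.counts.index,
                        columns=cm.counts.columns)
    size_factors = pd.Series(sf, index=cm.counts.columns, name="size_factor")
    return CountMatrix(norm, cm.dataset_id, cm.condition, cm.region), size_factors


def differential_expression(cm_a: CountMatrix, cm_b: CountMatrix,
                            fdr_threshold: float = 0.05,
                            lfc_threshold: float = 0.3) -> pd.DataFrame:
    """Per-gene Welch's t-test of B vs A on log2(normalized + 1).

    Both matrices must already be normalized and share a gene index. Returns
    a table with columns ``gene, log2fc, pvalue, fdr, direction, dataset_id``
    where direction is ``up``/``down`` only when fdr < ``fdr_threshold`` and
    |log2fc| > ``lfc_threshold``, else ``ns``. log2fc uses a 0.5 pseudocount
    on the group means. Degenerate-variance genes get p = 1 and are flagged.
    """
    if list(cm_a.genes) != list(cm_b.genes):
        raise ValueError("gene sets/order differ between conditions")
    if min(len(cm_a.samples), len(cm_b.samples)) < 2:
        raise ValueError("need >= 2 samples per condition")
    a = np.log2(cm_a.counts.to_numpy(dtype=float) + 1.0)
    b = np.log2(cm_b.counts.to_numpy(dtype=float) + 1.0)
    mean_a = cm_a.counts.mean(axis=1).to_numpy()
    mean_b = cm_b.counts.mean(axis=1).to_numpy()
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))

    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(b, a, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals) | degenerate, 1.0, pvals)
    fdr = multipletests(pvals, method="fdr_bh")[1]

    direction = np.where(
        (fdr < fdr_threshold) & (np.abs(log2fc) > lfc_threshold),
        np.where(log2fc > 0, "up", "down"), "ns")
    return pd.DataFrame({
        "gene": cm_a.genes, "log2fc": log2fc, "pvalue": pvals, "fdr": fdr,
        "direction": direction, "degenerate": degenerate,
        "dataset_id": cm_a.dataset_id,
    })


def consensus_degs(tables: list[pd.DataFrame]) -> pd.Series:
    """Genes significant with the same direction in *every* table.

    Returns a Series gene -> direction ("up"/"down"); the consensus set is
    by construction a subset of each table's significant set.
    """
    if not tables:
        raise ValueError("need at least one DE table")
    sig = []
    for t in tables:
        s = t.loc[t["direction"] != "ns"].set_index("gene")["direction"]
        sig.append(s)
    common = set(sig[0].index)
    for s in sig[1:]:
        common &= set(s.index)
    out = {}
    for g in sorted(common):
        dirs = {s[g] for s in sig}
        if len(dirs) == 1:
            out[g] = dirs.pop()
    return pd.Series(out, name="direction", dtype=object)
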