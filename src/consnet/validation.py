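"""Statistical evaluation: overlap coefficient, permutation test, Fisher test.

The Szymkiewicz-Simpson (overlap) coefficient |A ∩ B| / min(|A|, |B|)
normalizes an intersection by the smaller set, accommodating large size
disparities between the two assignment pools. Its significance is assessed
by permutation: sets of the observed sizes are redrawn from each network's
full lncRNA pool and the proportion of permuted coefficients at or above
the observed one is the p-value (reported as a bound "< 1/n_perm" when no
permutation reaches it). Core lncRNA enrichment between two networks is a
two-sided Fisher's exact test on the lncRNA/protein-coding contingency
table with the cross-product odds ratio.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["szymkiewicz_simpson", "permutation_overlap_test",
           "core_lncrna_enrichment", "OverlapTest", "FisherResult"]


def szymkiewicz_simpson(a: set, b: set) -> float:
    """|A ∩ B| / min(|A|, |B|); errors on empty input."""
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


@dataclass
class OverlapTest:
    observed: float
    n_perm: int
    count_ge: int
    p_value: float          # count_ge / n_perm (lower bound 1/n_perm when 0)
    p_report: str           # printable form, e.g. "0.0123" or "< 1e-04"
    seed: int


def permutation_overlap_test(a: set, b: set, pool_a: set, pool_b: set,
                             n_perm: int = 10_000, seed: int = 0) -> OverlapTest:
    """Permutation null for the overlap coefficient of two assigned sets.

    Each permutation draws |A| lncRNAs from pool_a and |B| from pool_b
    without replacement and recomputes the coefficient; p is the proportion
    of permutations with coefficient >= observed.
    """
    if not a <= pool_a or not b <= pool_b:
        raise ValueError("sets must be subsets of their pools")
    observed = szymkiewicz_simpson(a, b)
    rng = np.random.default_rng(seed)
    pa = np.array(sorted(pool_a), dtype=object)
    pb = np.array(sorted(pool_b), dtype=object)
    denom = min(len(a), len(b))
    count_ge = 0
    for _ in range(n_perm):
        sa = set(rng.choice(pa, size=len(a), replace=False))
        sb = set(rng.choice(pb, size=len(b), replace=False))
        if len(sa & sb) / denom >= observed:
            count_ge += 1
    if count_ge == 0:
        p = 1.0 / n_perm
        report = f"< {1.0 / n_perm:.0e}"
    else:
        p = count_ge / n_perm
        report = f"{p:.4g}"
    return OverlapTest(observed, n_perm, count_ge, p, report, seed)


@dataclass
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float       # cross-product (n11*n22)/(n12*n21)
    p_value: float          # two-sided exact


def core_lncrna_enrichment(core_a: tuple[int, int],
                           core_b: tuple[int, int]) -> FisherResult:
    """Fisher's exact test of lncRNA representation between two core sets.

    ``core_a`` and ``core_b`` are (n_lncRNA, n_protein_coding) counts; the
    two-sided p sums the probabilities of all tables at most as likely as
    the observed one.
    """
    table = np.array([core_a, core_b], dtype=int)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return FisherResult(((int(table[0, 0]), int(table[0, 1])),
                         (int(table[1, 0]), int(table[1, 1]))),
                        float(odds), float(p))
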