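"""Set-association statistics: KS profile comparison, hypergeometric Venn
overlap, Fisher 2x2 association, upset intersection counts, and gene-set
(category) enrichment.

All exact tests use the conventional definitions: the hypergeometric
overlap p is the upper tail P(X >= k); the Fisher two-sided p sums the
point probabilities of all tables with the observed margins whose
probability does not exceed the observed table's.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .model import ValidationError


@dataclass(frozen=True)
class OverlapTestResult:
    test: str  # hypergeometric | fisher | ks
    statistic: float
    p_value: float
    inputs: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p_value outside [0, 1]")


def ks_compare_profiles(
    offsets_a: Sequence[float], offsets_b: Sequence[float]
) -> OverlapTestResult:
    """Two-sample Kolmogorov-Smirnov test between two offset distributions."""
    a = np.asarray(offsets_a, dtype=float)
    b = np.asarray(offsets_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("each side needs >= 1 observation")
    res = stats.ks_2samp(a, b, method="asymp")
    return OverlapTestResult("ks", float(res.statistic), float(res.pvalue),
                             (a.size, b.size))


def hypergeometric_overlap(k: int, n1: int, n2: int, N: int) -> OverlapTestResult:
    """Upper-tail P(X >= k) for the overlap of two sets in a universe of N.

    X ~ Hypergeometric(N, n1, n2): draw n2 elements without replacement
    from a universe containing n1 marked ones.
    """
    if not (0 <= k <= min(n1, n2) and 0 <= n1 <= N and 0 <= n2 <= N):
        raise ValidationError(f"inconsistent sizes k={k}, n1={n1}, n2={n2}, N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, n1, n2))
    return OverlapTestResult("hypergeometric", float(k), min(1.0, p), (k, n1, n2, N))


def fisher_association(table: Sequence[Sequence[int]]) -> OverlapTestResult:
    """Two-sided Fisher exact test on a 2x2 table; statistic is the odds ratio."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a 2x2 table of non-negative integers")
    if t.sum() == 0:
        raise ValidationError("all-zero table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return OverlapTestResult("fisher", float(odds), float(min(1.0, p)),
                             tuple(int(x) for x in t.ravel()))


def upset_counts(sets: Mapping[str, Set[str]]) -> Dict[Tuple[int, ...], int]:
    """Exclusive-intersection counts for every non-empty membership pattern.

    Keys are 0/1 tuples ordered like ``sets``; values sum to the size of
    the union.  Patterns with zero members are included (value 0) so the
    table always has 2**n - 1 rows.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValidationError("need >= 2 sets")
    universe = set().union(*sets.values())
    counts: Dict[Tuple[int, ...], int] = {}
    n = len(names)
    for code in range(1, 2**n):
        pattern = tuple((code >> (n - 1 - i)) & 1 for i in range(n))
        counts[pattern] = 0
    for el in universe:
        pattern = tuple(1 if el in sets[name] else 0 for name in names)
        counts[pattern] += 1
    return counts


def geneset_enrichment(
    target: Set[str],
    categories: Mapping[str, Set[str]],
    universe: Set[str],
    adjust: bool = False,
) -> List[Tuple[str, int, OverlapTestResult, float]]:
    """Hypergeometric enrichment of ``target`` in each category.

    Categories must be subsets of the universe; so must the target.
    Returns (category, overlap size, test result, adjusted p) sorted by p.
    With ``adjust`` the last field is the Benjamini-Hochberg q-value,
    otherwise it repeats the raw p.
    """
    if not target <= universe:
        raise ValidationError("target genes must lie within the universe")
    for name, cat in categories.items():
        if not cat <= universe:
            raise ValidationError(f"category {name!r} not a subset of the universe")
    rows = []
    for name, cat in categories.items():
        k = len(target & cat)
        res = hypergeometric_overlap(k, len(cat), len(target), len(universe))
        rows.append((name, k, res))
    pvals = np.array([r[2].p_value for r in rows])
    if adjust and len(pvals):
        q = stats.false_discovery_control(pvals, method="bh")
    else:
        q = pvals
    out = [(name, k, res, float(qi)) for (name, k, res), qi in zip(rows, q)]
    out.sort(key=lambda r: r[2].p_value)
    return out
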