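"""RPKM computation and negative-binomial differential expression.

Genes are called differentially expressed between two groups when the
raw p-value is below ``p_threshold`` (default 0.01) and the fold change of
size-factor-normalized means is at least ``fc_threshold`` (default 2).
The test is an exact conditional test under a common-dispersion negative
binomial model: conditional on the total count of a gene, the split between
the two groups follows a beta-binomial law with weights n_g / phi (the
group sample counts over the dispersion), whose phi -> 0 limit is the
conditional binomial (Poisson) test.  Dispersion is a method-of-moments
estimate pooled across genes.  No multiple-testing correction is applied
by default; Benjamini-Hochberg is available behind a flag.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import false_discovery_control

from .model import CountMatrix, SampleDesign, ValidationError


@dataclass(frozen=True)
class ExpressionResult:
    gene_id: str
    mean_count_a: float
    mean_count_b: float
    log2_fold_change: float  # b over a
    p_value: float
    is_deg: bool
    direction: str  # up | down | none


def compute_rpkm(matrix: CountMatrix, gene_lengths: Dict[str, int]) -> pd.DataFrame:
    """Reads per kilobase of gene per million mapped reads, per gene x sample."""
    missing = [g for g in matrix.row_ids if g not in gene_lengths]
    if missing:
        raise ValidationError(f"missing gene length for {missing[:5]}")
    lengths_kb = np.array([gene_lengths[g] for g in matrix.row_ids], dtype=float) / 1e3
    if (lengths_kb <= 0).any():
        raise ValidationError("gene lengths must be > 0")
    per_million = matrix.library_sizes / 1e6
    rpkm = matrix.counts / lengths_kb[:, None] / per_million[None, :]
    return pd.DataFrame(rpkm, index=matrix.row_ids, columns=matrix.sample_ids)


def estimate_common_dispersion(matrix: CountMatrix, groups: Sequence[str]) -> float:
    """Pooled method-of-moments NB dispersion.

    For each gene, within-group mean m and unbiased variance s^2 give the
    moment estimate (s^2 - m) / m^2; the common dispersion is the average
    over genes with positive mean, floored at zero.  Averaging the raw
    (unfloored) estimates keeps the pooled value nearly unbiased at small
    replicate counts, where the sampling distribution of s^2 is strongly
    right-skewed.  Requires at least one group with two or more replicates.
    """
    groups = np.asarray(groups)
    if len(groups) != len(matrix.sample_ids):
        raise ValidationError("groups length must match sample count")
    replicated = [g for g in np.unique(groups) if (groups == g).sum() >= 2]
    if not replicated:
        raise ValidationError(
            "no group has >= 2 replicates; supply a dispersion explicitly"
        )
    ests = []
    for g in replicated:
        sub = matrix.counts[:, groups == g].astype(float)
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = m > 0
        ests.append((s2[ok] - m[ok]) / m[ok] ** 2)
    pooled = np.concatenate(ests)
    return float(max(0.0, np.mean(pooled))) if pooled.size else 0.0


def _conditional_log_pmf(T: int, r_a: float, r_b: float) -> np.ndarray:
    """log P(Y_a = y | Y_a + Y_b = T) for y = 0..T under shared NB success prob.

    With Y_a ~ NB(r_a, p) and Y_b ~ NB(r_b, p) independent, the conditional
    law is beta-binomial-like and parameter-free in p.
    """
    y = np.arange(T + 1)
    lp = (
        gammaln(y + r_a) - gammaln(y + 1) - gammaln(r_a)
        + gammaln(T - y + r_b) - gammaln(T - y + 1) - gammaln(r_b)
        - (gammaln(T + r_a + r_b) - gammaln(T + 1) - gammaln(r_a + r_b))
    )
    return lp


def _binomial_log_pmf(T: int, pi_a: float) -> np.ndarray:
    y = np.arange(T + 1)
    return (
        gammaln(T + 1) - gammaln(y + 1) - gammaln(T - y + 1)
        + y * np.log(pi_a) + (T - y) * np.log1p(-pi_a)
    )


def nb_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    dispersion: float,
    norm_factors: Optional[Sequence[float]] = None,
) -> float:
    """Two-sided exact conditional p-value for equal NB group means.

    ``norm_factors`` are per-sample relative size factors ordered as
    counts_a then counts_b; unequal factors are handled by rescaling counts
    to the mean factor (rounded), after which exact conditioning applies.
    The two-sided p sums all conditional outcomes whose point probability
    does not exceed the observed one.  An all-zero gene returns p = 1.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("each side needs >= 1 sample")
    if norm_factors is not None:
        f = np.asarray(norm_factors, dtype=float)
        if f.size != a.size + b.size or (f <= 0).any():
            raise ValidationError("norm_factors must be positive, one per sample")
        f = f / f.mean()
        a = np.round(a / f[: a.size])
        b = np.round(b / f[a.size:])
    ya, yb = int(a.sum()), int(b.sum())
    T = ya + yb
    if T == 0:
        return 1.0
    na, nb = a.size, b.size
    if dispersion <= 0:
        lp = _binomial_log_pmf(T, na / (na + nb))
    else:
        lp = _conditional_log_pmf(T, na / dispersion, nb / dispersion)
    obs = lp[ya]
    p = np.exp(lp[lp <= obs + 1e-9]).sum()
    return float(min(1.0, p))


def _size_factors(matrix: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors (robust to asymmetric regulation).

    Raw library sizes are distorted when regulation is one-sided — a block
    of strongly up-regulated genes inflates its group's totals and makes
    every other gene look down-regulated.  The median ratio to the
    per-gene geometric mean tracks the majority of unchanged genes instead.
    Falls back to library sizes when no gene is expressed in all samples.
    """
    counts = matrix.counts.astype(float)
    with np.errstate(divide="ignore"):
        logs = np.log(counts)
    finite = np.all(np.isfinite(logs), axis=1)
    if finite.sum() >= 10:
        ref = logs[finite].mean(axis=1)
        factors = np.exp(np.median(logs[finite] - ref[:, None], axis=0))
    else:
        factors = matrix.library_sizes.astype(float)
    return factors / factors.mean()


def call_degs(
    matrix: CountMatrix,
    design: Sequence[SampleDesign],
    group_a: Dict[str, str],
    group_b: Dict[str, str],
    p_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    dispersion: Optional[float] = None,
    adjust: bool = False,
) -> List[ExpressionResult]:
    """Call DEGs between two groups selected from the design.

    ``group_a`` / ``group_b`` are attribute filters such as
    ``{"age_group": "13m", "hemisphere": "contra"}``; samples matching each
    (with assay "rna" unless specified) form the two groups.  Fold change is
    computed on size-factor-normalized means with a pseudocount of 0.5 on
    both means; direction "up" means higher in group B.  With
    ``adjust=True`` the p threshold is applied to BH-adjusted p-values.
    """

    def _select(flt: Dict[str, str]) -> List[str]:
        flt = dict(flt)
        flt.setdefault("assay", "rna")
        return [
            d.sample_id
            for d in design
            if all(getattr(d, k) == v for k, v in flt.items())
            and d.sample_id in matrix.sample_ids
        ]

    samples_a, samples_b = _select(group_a), _select(group_b)
    if not samples_a or not samples_b:
        raise ValidationError("each group must select at least one sample")
    idx_a = [matrix.sample_ids.index(s) for s in samples_a]
    idx_b = [matrix.sample_ids.index(s) for s in samples_b]
    factors = _size_factors(matrix)
    if dispersion is None:
        sub = matrix.subset_samples(samples_a + samples_b)
        dispersion = estimate_common_dispersion(
            sub, ["a"] * len(samples_a) + ["b"] * len(samples_b)
        )

    norm = matrix.counts / factors[None, :]
    results: List[ExpressionResult] = []
    pvals = np.empty(len(matrix.row_ids))
    lfcs = np.empty(len(matrix.row_ids))
    means_a = norm[:, idx_a].mean(axis=1)
    means_b = norm[:, idx_b].mean(axis=1)
    nf = np.concatenate([factors[idx_a], factors[idx_b]])
    for i in range(len(matrix.row_ids)):
        pvals[i] = nb_test(
            matrix.counts[i, idx_a], matrix.counts[i, idx_b], dispersion, nf
        )
        lfcs[i] = np.log2((means_b[i] + 0.5) / (means_a[i] + 0.5))
    crit = false_discovery_control(pvals, method="bh") if adjust else pvals
    for i, gid in enumerate(matrix.row_ids):
        is_deg = bool(crit[i] < p_threshold and abs(lfcs[i]) >= np.log2(fc_threshold))
        direction = "none"
        if is_deg:
            direction = "up" if lfcs[i] > 0 else "down"
        results.append(
            ExpressionResult(
                gid, float(means_a[i]), float(means_b[i]),
                float(lfcs[i]), float(pvals[i]), is_deg, direction,
            )
        )
    return results


def results_to_frame(results: Sequence[ExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene_id, r.mean_count_a, r.mean_count_b, r.log2_fold_change,
             r.p_value, r.is_deg, r.direction)
            for r in results
        ],
        columns=[
            "gene_id", "mean_count_a", "mean_count_b", "log2_fold_change",
            "p_value", "is_deg", "direction",
        ],
    )
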