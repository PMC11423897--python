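"""Rank-based one-tailed tests on rarefied richness distributions.

Two constructions are exposed, both built from the shared-quota replicate
lists of a pair of strata: a two-sample Wilcoxon rank-sum (Mann–Whitney)
test comparing the two replicate richness lists, and a one-sample Wilcoxon
signed-rank test on the per-replicate differences.

A statistical health warning applies to both: rarefaction replicates are
pseudo-replicates of a single underlying dataset, not independent samples,
so with thousands of replicates the p-values become arbitrarily small and
quantify resampling noise, not evidence strength.  Every result therefore
carries an explicit caveat field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Caveat attached to every result.
PSEUDOREPLICATE_CAVEAT = (
    "replicates are pseudo-replicates of one dataset; p-values shrink with "
    "the replicate count and must not be read as independent-sample evidence"
)

#: Exact-enumeration regime bounds (no ties): beyond these, the normal
#: approximation with tie and continuity corrections is used.
RANK_SUM_EXACT_LIMIT = 12  # n1 + n2
SIGNED_RANK_EXACT_LIMIT = 25  # n

_P_FLOOR = float(np.finfo(float).eps)


@dataclass
class TestResult:
    test: str  # 'two_sample_rank_sum' | 'one_sample_signed_rank'
    alternative: str  # 'greater' | 'less' | 'two-sided'
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str  # 'exact' | 'asymptotic'
    caveat: str = PSEUDOREPLICATE_CAVEAT


def _check_alternative(alternative: str) -> None:
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")


def rank_sum_test(x, y, alternative: str = "greater") -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test of ``x`` versus ``y``.

    Exact null enumeration when n1 + n2 <= 12 and the pooled sample is
    tie-free; otherwise the normal approximation with midrank tie correction
    and continuity correction.  ``alternative='greater'`` tests whether
    values of ``x`` tend to exceed those of ``y``.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size) <= RANK_SUM_EXACT_LIMIT and not has_ties
    res = stats.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        test="two_sample_rank_sum",
        alternative=alternative,
        statistic=float(res.statistic),
        p_value=max(float(res.pvalue), _P_FLOOR),
        n1=int(x.size),
        n2=int(y.size),
        method="exact" if exact else "asymptotic",
    )


def signed_rank_test(d, alternative: str = "greater") -> TestResult:
    """Wilcoxon signed-rank test of paired differences against location 0.

    Zero differences are dropped before ranking (the classical convention);
    if all differences are zero the distribution is degenerate and an error
    is raised.  Exact enumeration of the 2^n sign assignments when n <= 25
    and the absolute differences are tie-free; otherwise the normal
    approximation with tie and continuity corrections.
    """
    _check_alternative(alternative)
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty sample")
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("degenerate: all differences are zero")
    has_ties = np.unique(np.abs(d)).size < d.size
    exact = d.size <= SIGNED_RANK_EXACT_LIMIT and not has_ties
    res = stats.wilcoxon(
        d,
        alternative=alternative,
        method="exact" if exact else "approx",
        correction=not exact,
    )
    return TestResult(
        test="one_sample_signed_rank",
        alternative=alternative,
        statistic=float(res.statistic),
        p_value=max(float(res.pvalue), _P_FLOOR),
        n1=int(d.size),
        n2=0,
        method="exact" if exact else "asymptotic",
    )
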