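"""Rank and ANOVA tests reported by the pipeline, with a uniform result type.

Thin, explicitly parameterized front-ends over scipy.stats: exact small-
sample null distributions where feasible (signed-rank n <= 25 without ties),
tie-corrected normal approximations with continuity correction above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

EXACT_WILCOXON_MAX_N = 25


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    adjustment: str = "none"
    undefined: bool = False
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["n"] = list(self.n)
        return d


def wilcoxon_signed_rank(x, mu0: float = 0.0) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of H0: median(x) = mu0.

    Zero differences are dropped; the null is exact for n <= 25 when the
    absolute differences are untied, otherwise a continuity-corrected normal
    approximation is used.  All differences zero -> flagged undefined.
    """
    d = np.asarray(x, dtype=float) - mu0
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult("wilcoxon_signed_rank", np.nan, np.nan, (0,), undefined=True)
    exact = n <= EXACT_WILCOXON_MAX_N and np.unique(np.abs(d)).size == n
    res = sps.wilcoxon(
        d, method="exact" if exact else "approx", correction=not exact,
    )
    return TestResult(
        "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), (n,),
        extra={"method": "exact" if exact else "normal_approx"},
    )


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test (tie-corrected normal approximation,
    exact for small untied samples via scipy's automatic method choice)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue), (x.size, y.size))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p: min(1, m * p)."""
    return min(1.0, m * p)


def anova_bonferroni(groups) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t tests.

    ``groups`` is a sequence of >= 2 samples.  Returns the overall F test and
    one adjusted two-sample comparison per pair (m = number of pairs).
    Identical-constant input yields F = 0 with p = 1, flagged undefined.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
        if not np.isfinite(g).all():
            raise ValueError("non-finite values")
    ns = tuple(g.size for g in arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        overall = TestResult("one_way_anova", 0.0, 1.0, ns, undefined=True)
    else:
        f, p = sps.f_oneway(*arrays)
        overall = TestResult("one_way_anova", float(f), float(p), ns)
    pairs = [(i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))]
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        a, b = arrays[i], arrays[j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(a, b)
        pairwise.append(
            TestResult(
                "pairwise_t", float(t), bonferroni(float(p), m), (a.size, b.size),
                adjustment="bonferroni", extra={"pair": (i, j), "raw_p": float(p)},
            )
        )
    return overall, pairwise
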