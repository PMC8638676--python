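"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: exhaustive
enumeration for nested pairings and rank-test nulls, plain loops for
normalization and interval membership.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata

PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}
MIN_LOOP = 3


def bruteforce_fold_score(seq: str) -> int:
    """Maximum pair weight over ALL nested pairings, by direct enumeration."""
    seq = seq.upper().replace("T", "U")

    def rec(positions: tuple[int, ...]) -> int:
        if len(positions) < 2:
            return 0
        i = positions[0]
        best = rec(positions[1:])  # i unpaired
        for j in positions[1:]:
            w = PAIR_WEIGHT.get((seq[i], seq[j]))
            if w is None or j - i <= MIN_LOOP:
                continue
            inside = tuple(p for p in positions if i < p < j)
            outside = tuple(p for p in positions if p > j)
            best = max(best, w + rec(inside) + rec(outside))
        return best

    return rec(tuple(range(len(seq))))


def bruteforce_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios by explicit loops over genes and samples."""
    n_genes, n_samples = counts.shape
    refs = []
    for g in range(n_genes):
        row = counts[g]
        if all(v > 0 for v in row):
            log_sum = sum(np.log(v) for v in row)
            refs.append((g, np.exp(log_sum / n_samples)))
    factors = []
    for j in range(n_samples):
        ratios = sorted(counts[g, j] / ref for g, ref in refs)
        k = len(ratios)
        med = ratios[k // 2] if k % 2 == 1 else 0.5 * (ratios[k // 2 - 1] + ratios[k // 2])
        factors.append(med)
    return np.array(factors)


def bruteforce_wilcoxon(d: np.ndarray) -> tuple[float, float]:
    """Exact signed-rank statistic min(R+, R-) and two-sided p by enumerating
    all 2^n sign assignments (untied |d| assumed)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    r_plus = ranks[d > 0].sum()
    total = n * (n + 1) / 2
    null = np.array(
        [sum(r for s, r in zip(signs, ranks) if s) for signs in product([0, 1], repeat=n)]
    )
    lo, hi = min(r_plus, total - r_plus), max(r_plus, total - r_plus)
    if lo == hi:
        p = 1.0
    else:
        p = ((null <= lo).sum() + (null >= hi).sum()) / null.size
    return float(lo), float(p)


def bruteforce_mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """U by pairwise comparison and two-sided p by enumerating all group
    assignments of the pooled sample."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    pooled = np.concatenate([x, y])
    nx = x.size
    us = []
    for idx in combinations(range(pooled.size), nx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys))
    us = np.array(us)
    u_other = x.size * y.size - u_obs
    lo, hi = min(u_obs, u_other), max(u_obs, u_other)
    if lo == hi:
        p = 1.0
    else:
        p = ((us <= lo).sum() + (us >= hi).sum()) / us.size
    return float(u_obs), float(p)


def bruteforce_anova_f(groups) -> float:
    """One-way ANOVA F from hand-computed sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = all_vals.size - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)
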