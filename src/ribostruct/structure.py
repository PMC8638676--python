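"""5'UTR secondary-structure analyses.

Relates TE classification to predicted 5'UTR folding energy (kcal/mol, more
negative = more structured), stratifies genes by structural complexity, and
profiles per-nucleotide chemical-probing (icSHAPE-style) reactivity in a
window upstream of the start codon (low reactivity = likely base-paired).

Energy-group comparisons follow a size-matched random-control design: for
each TE group a control set of identical size is drawn uniformly without
replacement from the retained genes outside the group, so group-size
differences cannot bias the comparison.  The default two-group test is
Mann-Whitney (robust to the heavy left tail of folding energies); a one-way
ANOVA with Bonferroni-adjusted pairwise comparisons is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, anova_bonferroni, mann_whitney, wilcoxon_signed_rank
from .fold import FoldResult, fold_score  # re-exported; used by the simulator

__all__ = [
    "GroupComparisonResult", "group_energy_comparison", "stratify_by_energy",
    "StratumTestResult", "strata_delta_te_test", "top_mrna_control",
    "IcshapeGroupResult", "icshape_window_profile", "fold_score", "FoldResult",
    "COMPLEX_CUTOFF", "SIMPLE_CUTOFF",
]

COMPLEX_CUTOFF = -250.0  # kcal/mol; energies strictly below -> complex stratum
SIMPLE_CUTOFF = -20.0    # kcal/mol; energies strictly above -> simple stratum


@dataclass
class GroupComparisonResult:
    group: str
    n: int
    group_median: float
    group_mean: float
    control_median: float
    control_mean: float
    mannwhitney: TestResult
    anova: TestResult
    seed: int
    n_resample: int
    low_power: bool = False
    pairwise: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["mannwhitney"] = self.mannwhitney.as_dict()
        d["anova"] = self.anova.as_dict()
        d["pairwise"] = [t.as_dict() for t in self.pairwise]
        return d


def group_energy_comparison(
    labels: pd.Series,
    energies: pd.Series,
    rng_seed: int = 0,
    n_resample: int = 1,
    groups: Sequence[str] = ("up", "down"),
    min_group: int = 20,
) -> dict[str, GroupComparisonResult]:
    """Compare folding energy of each TE group against a size-matched control.

    ``labels`` maps gene -> {'up','down','neutral'}; ``energies`` maps
    gene -> folding energy.  Only genes present in both with finite energy
    are considered.  For each group a control of the same size is drawn
    uniformly without replacement from the remaining genes; with
    ``n_resample > 1`` the draw is repeated and the median p across draws is
    reported.  Deterministic given ``rng_seed``.
    """
    shared = labels.index.intersection(energies.index)
    energy = energies.loc[shared].astype(float)
    energy = energy[np.isfinite(energy)]
    labs = labels.loc[energy.index]
    results: dict[str, GroupComparisonResult] = {}
    for group in groups:
        group_tag = int.from_bytes(group.encode()[:4].ljust(4, b"\0"), "little")
        rng = np.random.default_rng([rng_seed, group_tag % (2**31)])
        members = energy.index[labs == group]
        pool = energy.index[labs != group]
        n = len(members)
        if n == 0 or len(pool) < n:
            continue
        g_vals = energy.loc[members].to_numpy()
        mw_ps, an_ps, controls = [], [], []
        for _ in range(max(1, n_resample)):
            ctrl_idx = rng.choice(len(pool), size=n, replace=False)
            c_vals = energy.loc[pool[ctrl_idx]].to_numpy()
            controls.append(c_vals)
            mw_ps.append(mann_whitney(g_vals, c_vals))
            an_ps.append(anova_bonferroni([g_vals, c_vals]))
        order = np.argsort([t.p_value for t in mw_ps])
        pick = order[len(order) // 2]  # median-p draw
        c_vals = controls[pick]
        overall, pairwise = an_ps[pick]
        results[group] = GroupComparisonResult(
            group=group, n=n,
            group_median=float(np.median(g_vals)), group_mean=float(g_vals.mean()),
            control_median=float(np.median(c_vals)), control_mean=float(c_vals.mean()),
            mannwhitney=mw_ps[pick], anova=overall, pairwise=pairwise,
            seed=rng_seed, n_resample=max(1, n_resample), low_power=n < min_group,
        )
    return results


def stratify_by_energy(
    energies: pd.Series,
    complex_cutoff: float = COMPLEX_CUTOFF,
    simple_cutoff: float = SIMPLE_CUTOFF,
) -> tuple[pd.Index, pd.Index]:
    """Split genes into complex (< complex_cutoff) and simple (> simple_cutoff)
    5'UTR strata.  Strict inequalities; the strata are disjoint and genes in
    between belong to neither."""
    e = energies.astype(float)
    complex_set = e.index[e < complex_cutoff]
    simple_set = e.index[e > simple_cutoff]
    return complex_set, simple_set


@dataclass
class StratumTestResult:
    stratum: str
    n: int
    median_delta_te: float
    test: TestResult

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["test"] = self.test.as_dict()
        return d


def strata_delta_te_test(
    stratum: pd.Index, delta_te: pd.Series, name: str = "stratum"
) -> StratumTestResult:
    """Wilcoxon signed-rank test of H0: median delta TE = 0 within a stratum."""
    vals = delta_te.loc[delta_te.index.intersection(stratum)].to_numpy(dtype=float)
    if vals.size < 10:
        raise ValueError(f"stratum {name!r} has {vals.size} genes; need >= 10")
    test = wilcoxon_signed_rank(vals, 0.0)
    return StratumTestResult(name, int(vals.size), float(np.median(vals)), test)


def top_mrna_control(delta_te: pd.Series, top_gene_set) -> StratumTestResult:
    """delta-TE location test restricted to 5' terminal-oligopyrimidine genes.

    5'TOP mRNAs are canonically regulated via 4E-BP phosphorylation; an
    unshifted TOP set argues against a generic initiation-factor mechanism.
    """
    return strata_delta_te_test(pd.Index(top_gene_set), delta_te, name="5'TOP")


@dataclass
class IcshapeGroupResult:
    group: str
    n_genes: int
    window_mean: float
    profile: np.ndarray
    test_vs_all: Optional[TestResult]


@dataclass
class IcshapeWindowResult:
    window: tuple[int, int]
    all_mean: float
    n_all: int
    all_profile: np.ndarray
    groups: dict[str, IcshapeGroupResult]
    gene_window_means: pd.Series


def icshape_window_profile(
    labels: pd.Series,
    reactivity: Mapping[str, np.ndarray],
    cds_start: Mapping[str, int],
    window: tuple[int, int] = (-100, 0),
    min_coverage: float = 0.5,
    groups: Sequence[str] = ("up", "down"),
    include_group_in_reference: bool = True,
) -> IcshapeWindowResult:
    """Reactivity profiles in a window 5' of the start codon, per TE group.

    ``reactivity[g]`` is the per-nucleotide vector over g's 5'UTR (transcript
    coordinates 0..cds_start).  The window covers positions
    ``cds_start+window[0] .. cds_start+window[1]-1`` (half-open at the start
    codon).  A gene is eligible iff values are present (finite) at >=
    ``min_coverage`` of window positions; per-gene window means average the
    available positions.  Each group's window means are compared with the
    all-genes reference by Mann-Whitney.
    """
    lo, hi = window
    width = hi - lo
    rows: dict[str, np.ndarray] = {}
    for g, vec in reactivity.items():
        start = cds_start.get(g)
        if start is None:
            continue
        vec = np.asarray(vec, dtype=float)
        win = np.full(width, np.nan)
        a = start + lo
        b = start + hi
        src_lo, src_hi = max(a, 0), min(b, vec.size)
        if src_hi > src_lo:
            win[src_lo - a : src_hi - a] = vec[src_lo:src_hi]
        if np.isfinite(win).sum() >= min_coverage * width:
            rows[g] = win
    if not rows:
        raise ValueError("no gene has sufficient reactivity coverage in the window")
    mat = pd.DataFrame.from_dict(rows, orient="index")
    gene_means = mat.mean(axis=1, skipna=True)
    all_profile = mat.mean(axis=0, skipna=True).to_numpy()
    labs = labels.reindex(mat.index)
    out_groups: dict[str, IcshapeGroupResult] = {}
    for group in groups:
        members = mat.index[labs == group]
        if len(members) == 0:
            continue
        sub = mat.loc[members]
        reference = gene_means if include_group_in_reference else gene_means.drop(members)
        test = None
        if len(members) >= 5 and len(reference) >= 5:
            test = mann_whitney(gene_means.loc[members].to_numpy(), reference.to_numpy())
        out_groups[group] = IcshapeGroupResult(
            group=group, n_genes=len(members),
            window_mean=float(gene_means.loc[members].mean()),
            profile=sub.mean(axis=0, skipna=True).to_numpy(), test_vs_all=test,
        )
    return IcshapeWindowResult(
        window=window, all_mean=float(gene_means.mean()), n_all=len(gene_means),
        all_profile=all_profile, groups=out_groups, gene_window_means=gene_means,
    )
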