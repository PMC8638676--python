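"""Ribosome footprint processing.

Length filtering, midpoint realignment, CDS-restricted counting, triplet
periodicity, per-gene occupancy profiles and the start-codon-proximal
depletion statistic.

Footprint collections are pandas DataFrames with columns
``reference, five_prime, length, strand, sample_id``.  ``five_prime`` is the
0-based coordinate of the 5'-most base of the read.  In transcript space
(reference = gene_id) strand is always '+', coordinates run 5'->3'.

Each footprint is realigned to the rounded half point of the read,
``5' end + floor(length/2)``; for the dominant even footprint lengths
(28, 30 nt) the floor equals the exact half.  Counting then asks whether this
midpoint falls inside a gene's CDS union, which makes footprint assignment
deterministic and approximately A-site-like; RNA-seq reads are instead
counted by any-base overlap with the CDS union.  Reads whose midpoint (or
overlap) hits more than one gene are discarded as ambiguous, mirroring
union-mode counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import UnionGeneModel

FOOTPRINT_COLUMNS = ["reference", "five_prime", "length", "strand", "sample_id"]

MIN_LENGTH = 25          # reads shorter than this are discarded outright
KEEP_RANGE = (26, 34)    # size-selected footprint range, inclusive
MIN_COUNT = 128          # per-library-type summed CDS count threshold


@dataclass(frozen=True)
class FootprintRecord:
    reference: str
    five_prime: int
    length: int
    strand: str = "+"
    sample_id: str = "sample"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("footprint length must be positive")
        if self.five_prime < 0:
            raise ValueError("five_prime must be >= 0")


def footprints_frame(records: Iterable[FootprintRecord]) -> pd.DataFrame:
    """Build a footprint table from individual records."""
    rows = [(r.reference, r.five_prime, r.length, r.strand, r.sample_id) for r in records]
    return pd.DataFrame(rows, columns=FOOTPRINT_COLUMNS)


@dataclass
class FilterReport:
    total: int = 0
    invalid_length: int = 0
    below_min_length: int = 0
    outside_keep_range: int = 0
    kept: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def preprocess_footprints(
    footprints: pd.DataFrame,
    min_len: int = MIN_LENGTH,
    keep_range: tuple[int, int] = KEEP_RANGE,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the footprint length filters.

    Reads shorter than ``min_len`` are discarded, then only lengths within
    ``keep_range`` (inclusive; the size-selection window) are kept.  The
    report counts removals per rule, applied in that order; non-positive
    lengths are rejected first.
    """
    report = FilterReport(total=len(footprints))
    lengths = footprints["length"].to_numpy()
    valid = lengths > 0
    report.invalid_length = int((~valid).sum())
    short = valid & (lengths < min_len)
    report.below_min_length = int(short.sum())
    lo, hi = keep_range
    keep = valid & ~short & (lengths >= lo) & (lengths <= hi)
    report.outside_keep_range = int((valid & ~short & ~keep).sum())
    report.kept = int(keep.sum())
    return footprints.loc[keep].reset_index(drop=True), report


def midpoint_realign(five_prime, length, strand="+"):
    """Realign a footprint to its rounded half point.

    ``5' end + floor(length/2)`` on the '+' strand; the strand-aware
    equivalent (``5' end - floor(length/2)``) in genomic space on '-'.
    Accepts scalars or aligned arrays.
    """
    half = np.asarray(length) // 2
    fp = np.asarray(five_prime)
    if np.isscalar(strand) or isinstance(strand, str):
        return fp + half if strand == "+" else fp - half
    sign = np.where(np.asarray(strand) == "+", 1, -1)
    return fp + sign * half


@dataclass
class CountReport:
    """Per-sample accounting of read fate during CDS counting.

    Invariant: assigned + ambiguous + outside_cds + unknown_reference = total.
    """

    total: dict = field(default_factory=dict)
    assigned: dict = field(default_factory=dict)
    ambiguous: dict = field(default_factory=dict)
    outside_cds: dict = field(default_factory=dict)
    unknown_reference: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: dict(v) for k, v in self.__dict__.items()}


def _cds_trees(models: Mapping[str, UnionGeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g, m in models.items():
        tree = trees.setdefault(m.reference, IntervalTree())
        for a, b in m.cds_union:
            tree[a:b] = g
    return trees


def count_cds(
    footprints: pd.DataFrame,
    models: Mapping[str, UnionGeneModel],
    rna_mode: bool = False,
    space: str = "transcript",
) -> tuple[pd.DataFrame, CountReport]:
    """Count reads restricted to CDS regions, per gene x sample.

    Footprint mode: a read is assigned to gene g iff its realigned midpoint
    lies in g's CDS union and no other gene's.  RNA mode: any-base overlap
    with exactly one gene's CDS union.  ``space`` is ``"transcript"``
    (reference column holds gene ids; strand ignored, coordinates 5'->3')
    or ``"genomic"``.
    """
    genes = list(models)
    samples = sorted(footprints["sample_id"].unique().tolist())
    counts = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"), columns=samples, dtype=np.int64)
    report = CountReport()
    for s in samples:
        report.total[s] = 0
        report.assigned[s] = 0
        report.ambiguous[s] = 0
        report.outside_cds[s] = 0
        report.unknown_reference[s] = 0

    if space == "transcript":
        for (ref, s), sub in footprints.groupby(["reference", "sample_id"], sort=False):
            report.total[s] += len(sub)
            model = models.get(ref)
            if model is None:
                report.unknown_reference[s] += len(sub)
                continue
            lo, hi = model.cds_start_tx, model.cds_end_tx
            fp = sub["five_prime"].to_numpy()
            ln = sub["length"].to_numpy()
            if rna_mode:
                inside = (fp < hi) & (fp + ln > lo)
            else:
                mid = fp + ln // 2
                inside = (mid >= lo) & (mid < hi)
            n_in = int(inside.sum())
            counts.at[ref, s] += n_in
            report.assigned[s] += n_in
            report.outside_cds[s] += len(sub) - n_in
        return counts, report

    if space != "genomic":
        raise ValueError("space must be 'transcript' or 'genomic'")
    trees = _cds_trees(models)
    for row in footprints.itertuples(index=False):
        s = row.sample_id
        report.total[s] += 1
        tree = trees.get(row.reference)
        if tree is None:
            report.unknown_reference[s] += 1
            continue
        if rna_mode:
            if row.strand == "+":
                lo, hi = row.five_prime, row.five_prime + row.length
            else:
                lo, hi = row.five_prime - row.length + 1, row.five_prime + 1
            hits = {iv.data for iv in tree.overlap(lo, hi)}
        else:
            mid = midpoint_realign(row.five_prime, row.length, row.strand)
            hits = {iv.data for iv in tree.at(mid)}
        if len(hits) == 1:
            counts.at[hits.pop(), s] += 1
            report.assigned[s] += 1
        elif len(hits) > 1:
            report.ambiguous[s] += 1
        else:
            report.outside_cds[s] += 1
    return counts, report


def min_count_filter(
    ribo: pd.DataFrame, rna: pd.DataFrame, threshold: int = MIN_COUNT
) -> pd.Index:
    """Genes whose summed CDS count is >= threshold in BOTH library types.

    The low-count rule discards genes with fewer than ``threshold`` reads;
    requiring both the footprint and the RNA table to pass guarantees TE is
    defined for every retained gene.
    """
    shared = ribo.index.intersection(rna.index)
    ribo_ok = ribo.loc[shared].sum(axis=1) >= threshold
    rna_ok = rna.loc[shared].sum(axis=1) >= threshold
    return shared[ribo_ok & rna_ok]


@dataclass
class PeriodicityProfile:
    """Triplet periodicity summary of realigned in-CDS midpoints."""

    frame_fractions: np.ndarray
    frame_counts: np.ndarray
    metagene: np.ndarray
    window: tuple[int, int]
    n_reads: int
    undefined: bool = False


def periodicity_profile(
    footprints: pd.DataFrame,
    models: Mapping[str, UnionGeneModel],
    window: tuple[int, int] = (-20, 200),
) -> PeriodicityProfile:
    """Reading-frame fractions and a metagene profile around the CDS start.

    Footprints must be in transcript space.  The frame of each in-CDS
    midpoint is ``(midpoint - cds_start_tx) mod 3``; the metagene vector sums
    midpoint counts per position relative to the CDS start over ``window``
    (inclusive bounds) across genes.
    """
    lo, hi = window
    size = hi - lo + 1
    metagene = np.zeros(size, dtype=np.int64)
    frame_counts = np.zeros(3, dtype=np.int64)
    for ref, sub in footprints.groupby("reference", sort=False):
        model = models.get(ref)
        if model is None or not model.cds_union:
            continue
        mid = sub["five_prime"].to_numpy() + sub["length"].to_numpy() // 2
        start, end = model.cds_start_tx, model.cds_end_tx
        in_cds = (mid >= start) & (mid < end)
        rel_all = mid - start
        frame_counts += np.bincount(rel_all[in_cds] % 3, minlength=3)
        in_win = (rel_all >= lo) & (rel_all <= hi)
        metagene += np.bincount(rel_all[in_win] - lo, minlength=size)
    n = int(frame_counts.sum())
    if n == 0:
        fractions = np.full(3, np.nan)
        return PeriodicityProfile(fractions, frame_counts, metagene, window, 0, undefined=True)
    return PeriodicityProfile(frame_counts / n, frame_counts, metagene, window, n)


@dataclass
class OccupancyProfile:
    """Per-position midpoint counts along one gene's transcript."""

    gene_id: str
    values: np.ndarray

    @property
    def n_reads(self) -> int:
        return int(self.values.sum())


def occupancy_profile(model: UnionGeneModel, footprints: pd.DataFrame) -> OccupancyProfile:
    """Histogram of realigned midpoints over [0, transcript_length)."""
    length = model.transcript_length
    sub = footprints[footprints["reference"] == model.gene_id]
    mid = sub["five_prime"].to_numpy() + sub["length"].to_numpy() // 2
    mid = mid[(mid >= 0) & (mid < length)]
    values = np.bincount(mid, minlength=length)
    return OccupancyProfile(model.gene_id, values)


@dataclass
class DepletionResult:
    gene_id: str
    score: Optional[float]
    p_value: Optional[float]
    n_utr5_reads: int
    window: tuple[int, int]
    reason: Optional[str] = None


# Realigned midpoints cannot populate the first floor(max_length/2) nt of a
# transcript (a >=26 nt read with 5' end at 0 has its midpoint at >=13), so
# the cap-proximal margin is excluded from the depletion background.
UTR5_MARGIN = 17


def depletion_score(
    profile: OccupancyProfile,
    cds_start_tx: int,
    window: tuple[int, int] = (-20, -15),
    min_utr5_reads: int = 50,
    n_permutations: int = 1000,
    utr5_margin: int = UTR5_MARGIN,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> DepletionResult:
    """Footprint depletion immediately upstream of the main-ORF start codon.

    score = mean occupancy inside ``window`` (positions relative to the CDS
    start, inclusive; default [-20,-15], the 6 nt centred 15-20 nt upstream)
    divided by mean occupancy over the rest of the 5'UTR (cap-proximal margin
    and window excluded).  A score well below 1 indicates depletion.  The
    one-sided p-value is empirical: windows of the same size are drawn
    uniformly from the eligible 5'UTR positions (equivalent to permuting
    positions within the gene) and ``p = (1 + #{perm <= observed}) / (n+1)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    gene = profile.gene_id
    utr5 = np.asarray(profile.values[:cds_start_tx], dtype=float)
    if cds_start_tx < 40:
        return DepletionResult(gene, None, None, int(utr5.sum()), window,
                               reason="5'UTR shorter than 40 nt")
    win_idx = np.arange(cds_start_tx + window[0], cds_start_tx + window[1] + 1)
    if win_idx[0] < utr5_margin:
        return DepletionResult(gene, None, None, int(utr5.sum()), window,
                               reason="window overlaps cap-proximal margin")
    eligible = np.arange(utr5_margin, cds_start_tx)
    n_reads = int(utr5[eligible].sum())
    if n_reads < min_utr5_reads:
        return DepletionResult(gene, None, None, n_reads, window,
                               reason=f"fewer than {min_utr5_reads} 5'UTR reads")
    in_win = np.isin(eligible, win_idx)
    vals = utr5[eligible]
    win_mean = vals[in_win].mean()
    bg_mean = vals[~in_win].mean()
    if bg_mean == 0:
        return DepletionResult(gene, None, None, n_reads, window,
                               reason="zero background coverage")
    score = float(win_mean / bg_mean)

    k = int(in_win.sum())
    total = vals.sum()
    n_pos = vals.size
    # draw k positions without replacement per permutation (top-k of uniforms)
    u = rng.random((n_permutations, n_pos))
    sel = np.argpartition(u, k - 1, axis=1)[:, :k]
    win_sums = vals[sel].sum(axis=1)
    w = win_sums / k
    b = (total - win_sums) / (n_pos - k)
    with np.errstate(divide="ignore"):
        perm_scores = np.where(b == 0, np.inf, w / b)
    p = float((1 + np.sum(perm_scores <= score)) / (n_permutations + 1))
    return DepletionResult(gene, score, p, n_reads, window)
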