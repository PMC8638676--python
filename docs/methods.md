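# Methods

## Pipeline overview

The analysis proceeds annotation → footprint processing → expression →
structure analysis.

**Annotation.** GTF (1-based closed) or BED12 (0-based half-open) input is
converted to internal 0-based half-open, strand-aware coordinates. To avoid
multiple counting across isoforms, each gene is reduced to one union model:
`exon_union` and `cds_union` are interval unions over all isoforms, and
transcript coordinates index the spliced exon union 5′→3′. Genes whose
isoforms disagree on strand or reference are dropped, not merged. The union
of CDS intervals (rather than, say, the longest isoform's CDS) was a design
choice; it is the natural completion of union-of-isoform exon counting, and
the alternative would only shrink the counting region.

**Footprint processing.** Reads shorter than 25 nt are discarded and
26–34 nt footprints retained (the size-selection window). Each footprint is
realigned to its rounded half point, `5′ end + floor(length/2)`;
`floor` is the resolution of "rounded" here — for the dominant even lengths
(28, 30 nt) it equals the exact half, and it is configurable. Footprints are
counted into a gene when the realigned midpoint falls in the gene's CDS
union and no other gene's (ambiguous midpoints are discarded and reported);
RNA-seq reads count by any-base overlap instead, mirroring union-mode
counting. Genes need ≥128 summed CDS reads in **both** the footprint and
the RNA table; requiring both guarantees TE is defined for every retained
gene. Per-sample accounting satisfies
`assigned + ambiguous + outside-CDS + unknown-reference = total`.

**Expression.** Median-of-ratios size factors: the per-gene reference is
the geometric mean of counts across samples (genes with any zero excluded);
a sample's factor is the median over genes of count/reference. Note the
factors are defined up to a common scale — multiplying one of *m* samples
by *c* moves its factor by `c^(1−1/m)` and the others by `c^(−1/m)`, so
normalized counts and TE shift by a common `c^(1/m)` while ΔTE, z and
labels are exactly invariant. TE per condition is the ratio of mean
normalized footprint counts to mean normalized RNA counts (no
pseudo-counts; positivity is guaranteed by the joint count filter, and
violations are dropped and logged). The full negative-binomial GLM of
dedicated differential-expression packages is intentionally not
reproduced: classification here is an empirical z score on ΔTE, not a
per-gene Wald test, so normalization + condition means suffice. z uses the
sample (n−1) SD; cutoffs are inclusive (|z| ≥ 1.5); all logs are base 2.

**Structure analysis.** Folding-energy comparisons follow a size-matched
random-control design: for each TE group, a control of identical size is
drawn uniformly without replacement from the retained genes outside the
group (seeded; optionally repeated, reporting the median-p draw). The
default two-group test is Mann–Whitney — folding energies have a heavy left
tail — with one-way ANOVA + Bonferroni pairwise reported alongside; both
conventions appear in the field and neither is presumed canonical. Strata
use strict inequalities (complex < −250, simple > −20 kcal/mol; a gene at
exactly −250 is in neither) and a two-sided Wilcoxon signed-rank test of
median ΔTE = 0. The same location test restricted to a user-supplied 5′TOP
gene list serves as a negative control. The icSHAPE window covers
positions `cds_start−100 .. cds_start−1`; a gene is eligible when ≥50% of
window positions carry finite reactivity (coverage handling after merging
external probing data is not standardized; 50% is this package's choice
and is configurable), per-gene means average available positions, and each
group's window means are compared to the all-genes reference (group genes
included in the reference by default, configurable).

**Positional diagnostics.** Triplet periodicity: the frame of each in-CDS
midpoint is `(midpoint − cds_start) mod 3`; the metagene profile spans
−20..+200 nt around the CDS start. The depletion score for a gene is the
mean occupancy inside the window −20..−15 nt (inclusive, 6 nt) upstream of
the main-ORF start divided by the mean over the rest of the 5′UTR. Two
boundary rules matter: the window bound choice (the literature phrase
"15–20 nt before" does not state inclusivity; both edges are configurable)
and a 17-nt cap-proximal exclusion — a realigned 26–34 nt footprint cannot
place its midpoint in the first `floor(length/2)` nt of a transcript, so
including that margin in the background would bias scores upward and break
the permutation null. The one-sided empirical p-value redraws same-size
windows uniformly from the eligible 5′UTR positions (equivalent to
permuting the per-position coverage vector), `p = (1 + #{perm ≤ obs})/(n+1)`
with 1000 seeded permutations by default; ties make it conservative by
about half the tie fraction, negligible at the read depths where the score
is reported at all (default minimum 50 5′UTR reads).

**Statistical tests.** Signed-rank p-values are exact (full 2^n null) for
n ≤ 25 without ties in |d|, otherwise a continuity-corrected normal
approximation; Mann–Whitney uses the tie-corrected normal approximation
with exact small-sample nulls where scipy's automatic rule allows; ANOVA is
the standard F with Bonferroni-adjusted pairwise t tests (adjusted
p = min(1, m·p)). All are two-sided.

## The synthetic-data generator

The generator emulates the statistical structure of a two-condition,
two-replicate brain ribo-seq/RNA-seq comparison so that every stage is
testable without downloads.

*Genes.* Single-isoform, single-exon models, one per synthetic contig
(keeping truth bookkeeping exact; multi-isoform union logic is tested on
hand-built fixtures). Lengths are lognormal: 5′UTR median 150 nt (σ=0.3,
log scale), CDS median 1,200 nt (σ=0.3, rounded to codons), 3′UTR median
250 nt. 15% of genes are "complex" (5′UTRs 2.5× longer — stems need
physical room — built by embedding 12–20 bp GC-biased reverse-complement
repeats), 15% "simple" (A/C-dominated, pairing-poor), the rest "mid"
(random sequence with composition biased away from perfect
complementarity). With the Nussinov pseudo-energy (below) at scale 1.0
this yields class medians near −430 / −125 / −12 kcal/mol, so the complex
and simple classes fall almost entirely inside the fixed −250/−20 strata
while mid genes rarely cross either cutoff.

*Fold score.* A Nussinov dynamic program maximizing total pair weight
(GC=3, AU=2, GU=1) with hairpin loops ≥3 nt; pseudo-energy = −score. This
is a combinatorial scoring model, deliberately *not* a thermodynamic MFE
predictor: it gives synthetic sequences internally consistent energies,
and measured folding-energy tables for real transcriptomes are consumed
unchanged. Reactivity tracks are `0.30 − 0.15·paired + N(0, 0.10)` clipped
at zero, with `paired` from the fold traceback — structured windows read
lower, matching the chemical-probing convention.

*Counts.* RNA counts ~ NB(mean = depth·expr_g·s_j, α) and footprint counts
~ NB(mean = depth·expr_g·TE_g,cond·s_j, α) with variance = μ + α·μ²,
α = 0.05 constant across genes (per-gene dispersion fitting is unnecessary
for recovery testing), depth 400 (median per-sample gene count),
per-gene expression 2^N(0,1), baseline TE 2^N(0,1.2), and lognormal
(σ=0.2) sample factors to exercise normalization. The planted shift `beta`
(+1 log2 by default) applies to the complex class, split ±β/2 around the
baseline so the contrast is symmetric. The baseline-TE spread was set by a
reproducibility argument: at α = 0.05 and depth 400 the per-replicate TE
noise is ≈0.47 log2 SD, and between-replicate Spearman correlation of
≈0.85 — typical of replicated ribo-seq — requires true TE variance several
times that noise; σ = 1.2 achieves it, and the choice cancels out of ΔTE
entirely.

*Footprints.* In-CDS midpoints sit at codon offsets with frame-0
probability 0.85; 5′UTR midpoints are uniform over the reachable region
(≥17 nt from the cap) except multiplied by 0.1 inside the −20..−15 window
for flagged genes; lengths are drawn from 26–34 nt with a 29–30 mode and
5′ ends back-computed so midpoint realignment reproduces the drawn
position exactly. Everything is deterministic given the seed.

*What the generator does not emulate:* multi-isoform genes, rRNA and
adapter contamination, sequence-dependent ligation/RT bias, per-gene
dispersion trends, correlated replicates, 3′UTR structure–TE coupling
(3′UTR energies are class-independent by design, serving as the negative
control), and thermodynamic folding. Passing tests therefore demonstrate
that the *computation* recovers planted effects under realistic count
noise — not that any biological claim holds in real libraries.

## Operating characteristics of the z classification

At the reference conditions (α = 0.05, depth 400, 2 replicates) the ΔTE
measurement noise has an SD floor of `sqrt(4·α/2)/ln2 ≈ 0.46` log2 — the
dispersion term does not average away with depth. A +1 log2 planted shift
on 15% of genes then yields an all-gene ΔTE SD near 0.60, putting the
z ≥ 1.5 threshold at ≈ +0.92, so the cutoff recovers roughly 45–50% of
planted two-fold shifts while keeping the false-positive rate near 1% and
the null TE-up fraction at the ≈6.7% normal-tail expectation. Detecting a
two-fold shift with higher sensitivity at this design size requires lower
dispersion (deeper, cleaner libraries: α ≲ 0.03) or more replicates, not a
different implementation; the z-cutoff rule trades sensitivity for a very
low false-positive rate by construction. A subtle consequence of
median-of-ratios normalization under asymmetric planting: null genes
absorb a small negative ΔTE offset (≈ −0.12 at β = +1), which is why the
simple stratum's median sits slightly below zero and the
complex-minus-simple contrast, where the offset cancels, recovers β almost
exactly.

## Numerical and degenerate-input conventions

- Interval convention everywhere: 0-based half-open; a midpoint exactly at
  `cds_end` is outside.
- Zero-SD ΔTE vectors classify everything neutral (with a warning) rather
  than erroring; all-zero signed-rank differences and identical-constant
  ANOVA inputs return flagged-undefined results with p = 1 where a value
  is needed.
- Size factors require at least one all-nonzero gene and instruct
  pre-filtering otherwise.
- Group-control resampling, depletion permutations and all simulation
  stages take explicit seeds; identical seeds reproduce byte-identical
  outputs, including the CLI's JSON summaries.
- The depletion score is reported as null (with a reason) for 5′UTRs
  shorter than 40 nt, fewer than 50 5′UTR reads, windows overlapping the
  cap margin, or zero background.

## Problem sizes

Default test and reproduction runs use 300–4,000 genes; the reference
simulation in `scripts/acceptance.py` uses 4,000 genes (≈0.8 M footprints,
eight count libraries), chosen so strata hold hundreds of genes and group
tests are far from their small-sample regimes while a full run stays in
the minutes range on one core. Null calibration repeats the count draw 50
times over one fixed transcriptome, since the calibration targets the
count → TE → classification chain, not sequence generation.
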