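# ribostruct

Ribosome-profiling analysis of translation efficiency and its relationship
to 5′UTR secondary structure, with a fully synthetic test bed.

## The problem

Ribosome profiling pairs deep sequencing of ribosome-protected mRNA
fragments (footprints, 26–34 nt) with matched RNA-seq. For a gene *g* the
**translation efficiency** is the ratio of its normalized footprint
abundance to its normalized mRNA abundance,

```
TE_g = (ribo_g / s_ribo) / (rna_g / s_rna),
```

with median-of-ratios size factors *s* per library. Comparing two
genotypes (case vs control), the per-gene shift is

```
ΔTE_g = log2 TE_g(case) − log2 TE_g(control),
```

and genes are called **TE-up** / **TE-down** when the standard z score of
ΔTE across genes passes ±1.5 (inclusive). The scientific question the
downstream modules address: are the shifted genes the ones with *stable
5′UTR secondary structure*? Three independent measures are used —
predicted 5′UTR folding energy (kcal/mol, more negative = more structured)
compared against size-matched random control gene sets; fixed energy
strata (complex < −250, simple > −20 kcal/mol) tested for opposite median
ΔTE by Wilcoxon signed-rank; and in-cell chemical-probing (icSHAPE-style)
reactivity in the −100..0 nt window upstream of the start codon, where low
reactivity means base-paired. Two positional diagnostics complete the
pipeline: triplet periodicity of footprint midpoints (library quality) and
a depletion score for footprint loss 15–20 nt before the main-ORF start
codon, the signature of upstream-ORF–regulated genes.

The package is aimed at labs analysing ribo-seq count data who want these
analyses reproducible and testable: every stage can be exercised on
synthetic data with known planted effects (negative-binomial counts,
structure-dependent TE shifts, periodic footprints, planted depletion), so
the whole pipeline is verified end to end without any download.

## Worked example

```bash
python examples/01_te_classification.py
```

```
genes retained after the >=128-count filter: 399
SD of TE differences (log2): 0.556
TE up: 31, TE down: 19, neutral: 349

five genes with the largest |z|:
         te_case  te_control  delta_te      z label
gene_id
g00045     2.794       0.596     2.228  3.943    up
g00096     3.284       1.048     1.648  2.899    up
...
```

31/399 ≈ 7.8% of genes exceed z ≥ 1.5, close to the 6.7% normal-tail
expectation plus the planted 15% of structured genes shifted by +1 log2.
`examples/02_structure_stratification.py` then ties the shift to
structure:

```
TE-up: n=55, median energy -405 kcal/mol vs control -119 (Mann-Whitney p=4.42e-09)
complex 5'UTR stratum: n=96, median delta TE +0.648 (signed-rank p=2.52e-13)
simple 5'UTR stratum: n=73, median delta TE -0.248 (signed-rank p=1.76e-03)
icSHAPE window mean, all genes: 0.212
  TE-up: 0.183 (vs all, p=1.63e-13)
```

TE-up genes carry far more negative folding energy than their size-matched
control and lower pre-start reactivity — the planted structure×condition
interaction, recovered. `examples/03_…` and `04_…` demonstrate the
periodicity/depletion diagnostics and the Nussinov-style fold score.

A thin CLI wraps the same flow for shell use:

```bash
ribostruct simulate --n-genes 2000 --seed 1 --outdir sim/
ribostruct run --annotation sim/annotation.gtf --ribo-counts sim/ribo_counts.tsv \
    --rna-counts sim/rna_counts.tsv --sample-sheet sim/samples.tsv \
    --energy-table sim/energies.tsv --footprints sim/footprints.tsv --outdir results/
```

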