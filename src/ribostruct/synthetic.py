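"""Synthetic ribosome-profiling data with known planted parameters.

Generates single-isoform gene models, 5'UTR/CDS sequences, folding-energy
and reactivity annotations, negative-binomial count tables and positional
footprint records so that every pipeline stage can be exercised end to end
without external downloads.  The generator emulates the statistical
structure of a two-condition (case vs control), two-replicate brain
ribo-seq/RNA-seq study: NB counts with sample-specific library factors, a
structure-dependent log2 TE shift planted on the most-structured genes,
3-nt periodic CDS footprint positions, and optional footprint depletion
15-20 nt upstream of the main-ORF start codon.

Gene classes
------------
A ``structured_fraction`` of genes ('complex') get long, stem-rich 5'UTRs
built by embedding reverse-complement GC-biased repeats; a
``simple_fraction`` get pairing-poor (A/C-rich) 5'UTRs; the rest ('mid') get
moderately pairable random sequence.  5'UTR folding energies are the
Nussinov pseudo-energies of the generated sequences, so the planted classes
are the most/least structured genes by construction rather than by fiat.
The planted TE shift (``beta``, log2) applies to the complex class only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .annotation import UnionGeneModel
from .fold import fold_score
from .footprints import FOOTPRINT_COLUMNS

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_NT = np.array(list("ACGU"))


@dataclass
class SimulationConfig:
    """Study conditions for the simulator (defaults are the reference design)."""

    n_genes: int = 2000
    # lognormal length distributions (median in nt, sigma on the log scale)
    utr5_median: float = 150.0
    utr5_sigma: float = 0.3
    cds_median: float = 1200.0
    cds_sigma: float = 0.3
    utr3_median: float = 250.0
    utr3_sigma: float = 0.3
    # 5'UTRs of complex-class genes are this much longer (structured UTRs
    # need physical room for stems to clear the complex-stratum cutoff)
    complex_utr5_scale: float = 2.5
    # count model
    n_replicates: int = 2           # per condition per library type
    depth: float = 400.0            # target median per-sample gene count
    dispersion: float = 0.05        # NB: var = mu + dispersion * mu^2
    expression_sigma: float = 1.0   # log2 SD of per-gene baseline expression
    base_te_sigma: float = 1.2      # log2 SD of per-gene baseline TE
    library_factor_sigma: float = 0.2  # log SD of sample-specific factors
    # planted effect
    beta: float = 1.0               # log2 TE shift on structured genes
    structured_fraction: float = 0.15
    simple_fraction: float = 0.15
    top_fraction: float = 0.05      # 5'TOP flag on unshifted genes
    # structure annotation
    energy_scale: float = 1.0       # kcal/mol per unit of fold score
    reactivity_base: float = 0.30
    reactivity_pair_penalty: float = 0.15
    reactivity_noise_sd: float = 0.10
    # footprints
    periodicity_p: float = 0.85     # frame-0 probability of CDS midpoints
    footprints_per_gene: float = 200.0
    utr5_footprints_per_gene: float = 200.0
    depletion_genes: int = 50
    depletion_factor: float = 0.1   # window coverage multiplier
    depletion_window: tuple[int, int] = (-20, -15)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.structured_fraction + self.simple_fraction <= 1:
            raise ValueError("class fractions must sum to <= 1")
        for name in ("utr5_median", "cds_median", "utr3_median", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.periodicity_p <= 1:
            raise ValueError("periodicity_p must be in [0,1]")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class GeneSequences:
    utr5: str
    cds: str
    utr3: str

    @property
    def transcript(self) -> str:
        return self.utr5 + self.cds + self.utr3


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulation run produces."""

    config: SimulationConfig
    models: dict[str, UnionGeneModel]
    sequences: dict[str, GeneSequences]
    truth: pd.DataFrame
    structure: pd.DataFrame = None
    reactivity: dict[str, np.ndarray] = field(default_factory=dict)
    ribo: pd.DataFrame = None
    rna: pd.DataFrame = None
    sample_sheet: pd.DataFrame = None
    footprints: pd.DataFrame = None


def _lognormal_lengths(rng, n, median, sigma, minimum, multiple_of=1):
    raw = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
    lengths = np.maximum(minimum, np.round(raw).astype(int))
    if multiple_of > 1:
        lengths = (lengths // multiple_of) * multiple_of
        lengths = np.maximum(minimum, lengths)
    return lengths


def _random_seq(rng, length, probs):
    return "".join(rng.choice(_NT, size=length, p=probs))


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def _structured_utr5(rng, length: int) -> str:
    """Stem-rich 5'UTR: GC-biased stems embedded as reverse-complement repeats."""
    parts: list[str] = []
    total = 0
    stem_probs = [0.10, 0.40, 0.40, 0.10]  # A C G U
    while total < length:
        if rng.random() < 0.75 and length - total >= 30:
            stem_len = int(rng.integers(12, 21))
            loop_len = int(rng.integers(3, 7))
            stem = _random_seq(rng, stem_len, stem_probs)
            loop = _random_seq(rng, loop_len, [0.4, 0.2, 0.1, 0.3])
            block = stem + loop + _revcomp(stem)
        else:
            block = _random_seq(rng, int(rng.integers(5, 16)), [0.25, 0.25, 0.25, 0.25])
        parts.append(block)
        total += len(block)
    return "".join(parts)[:length]


def _simple_utr5(rng, length: int) -> str:
    """Pairing-poor 5'UTR: A/C-dominated with a trace of U, no G."""
    return _random_seq(rng, length, [0.58, 0.38, 0.0, 0.04])


def _mid_utr5(rng, length: int) -> str:
    """Moderately pairable random sequence (composition biased away from
    perfect complementarity so energies fall between the strata cutoffs)."""
    return _random_seq(rng, length, [0.35, 0.25, 0.20, 0.20])


def simulate_transcriptome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, UnionGeneModel], dict[str, GeneSequences], pd.DataFrame]:
    """Gene models + sequences + the initial truth table.

    Every gene is a single-exon, single-isoform model on its own reference
    contig (named after the gene), which keeps truth bookkeeping exact; the
    union-of-isoforms logic is exercised separately on hand-built fixtures.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    classes = np.full(n, "mid", dtype=object)
    n_complex = int(round(config.structured_fraction * n))
    n_simple = int(round(config.simple_fraction * n))
    order = rng.permutation(n)
    classes[order[:n_complex]] = "complex"
    classes[order[n_complex : n_complex + n_simple]] = "simple"

    utr5_len = _lognormal_lengths(rng, n, config.utr5_median, config.utr5_sigma, 40)
    utr5_len = np.where(
        classes == "complex",
        np.round(utr5_len * config.complex_utr5_scale).astype(int),
        utr5_len,
    )
    cds_len = _lognormal_lengths(rng, n, config.cds_median, config.cds_sigma, 60, multiple_of=3)
    utr3_len = _lognormal_lengths(rng, n, config.utr3_median, config.utr3_sigma, 30)

    models: dict[str, UnionGeneModel] = {}
    sequences: dict[str, GeneSequences] = {}
    uniform = [0.25, 0.25, 0.25, 0.25]
    for i, g in enumerate(gene_ids):
        u5, c, u3 = int(utr5_len[i]), int(cds_len[i]), int(utr3_len[i])
        if classes[i] == "complex":
            utr5 = _structured_utr5(rng, u5)
        elif classes[i] == "simple":
            utr5 = _simple_utr5(rng, u5)
        else:
            utr5 = _mid_utr5(rng, u5)
        cds = "AUG" + _random_seq(rng, c - 6, uniform) + "UAA"
        utr3 = _random_seq(rng, u3, uniform)
        total = u5 + c + u3
        models[g] = UnionGeneModel(
            gene_id=g, reference=g, strand="+",
            exon_union=((0, total),), cds_union=((u5, u5 + c),),
        )
        sequences[g] = GeneSequences(utr5, cds, utr3)

    depleted = np.zeros(n, dtype=bool)
    candidates = np.flatnonzero(utr5_len >= 60)
    n_dep = min(config.depletion_genes, candidates.size)
    if n_dep > 0:
        depleted[rng.choice(candidates, size=n_dep, replace=False)] = True
    top = np.zeros(n, dtype=bool)
    null_genes = np.flatnonzero(classes != "complex")
    n_top = int(round(config.top_fraction * n))
    if n_top > 0 and null_genes.size >= n_top:
        top[rng.choice(null_genes, size=n_top, replace=False)] = True

    truth = pd.DataFrame(
        {
            "structure_class": classes,
            "utr5_length": utr5_len,
            "cds_length": cds_len,
            "utr3_length": utr3_len,
            "delta_te": np.where(classes == "complex", config.beta, 0.0),
            "depleted": depleted,
            "top": top,
            "expression": 2.0 ** rng.normal(0.0, config.expression_sigma, size=n),
            "base_te": 2.0 ** rng.normal(0.0, config.base_te_sigma, size=n),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return models, sequences, truth


def simulate_structure(
    models: Mapping[str, UnionGeneModel],
    sequences: Mapping[str, GeneSequences],
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Folding-energy table and per-nucleotide reactivity tracks.

    utr5_energy (and utr3_energy) are the Nussinov pseudo-energies of the
    generated sequences scaled by ``energy_scale``.  Reactivity over the
    5'UTR is ``reactivity_base`` minus ``reactivity_pair_penalty`` at
    positions paired in the fold traceback, plus Gaussian noise (clipped at
    zero) -- structured windows therefore get LOWER reactivity, matching the
    chemical-probing convention.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    genes = list(models)
    utr5_energy = np.empty(len(genes))
    utr3_energy = np.empty(len(genes))
    reactivity: dict[str, np.ndarray] = {}
    for i, g in enumerate(genes):
        seqs = sequences[g]
        res5 = fold_score(seqs.utr5)
        utr5_energy[i] = res5.pseudo_energy * config.energy_scale
        utr3_energy[i] = fold_score(seqs.utr3).pseudo_energy * config.energy_scale
        base = np.full(len(seqs.utr5), config.reactivity_base)
        base[res5.paired_mask] -= config.reactivity_pair_penalty
        noise = rng.normal(0.0, config.reactivity_noise_sd, size=base.size)
        reactivity[g] = np.clip(base + noise, 0.0, None)
    structure = pd.DataFrame(
        {"utr5_energy": utr5_energy, "utr3_energy": utr3_energy},
        index=pd.Index(genes, name="gene_id"),
    )
    truth.loc[genes, "utr5_energy"] = utr5_energy
    return structure, reactivity


def _nb_draw(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    models: Mapping[str, UnionGeneModel],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """NB ribo/RNA count tables plus the sample sheet.

    RNA counts have mean depth * expression_g * s_j; footprint counts have
    mean depth * expression_g * TE_g,cond * s_j with
    log2 TE(case) - log2 TE(control) equal to the planted delta_te (split
    symmetrically, +/- delta/2, around the baseline TE).  Sample-specific
    factors s_j are lognormal to exercise normalization.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    genes = truth.index
    expr = truth["expression"].to_numpy()
    base_te = truth["base_te"].to_numpy()
    delta = truth["delta_te"].to_numpy()
    conditions = ["control", "case"]
    rows = []
    ribo_cols: dict[str, np.ndarray] = {}
    rna_cols: dict[str, np.ndarray] = {}
    for lib, cols in (("ribo", ribo_cols), ("rna", rna_cols)):
        for cond in conditions:
            for rep in range(1, config.n_replicates + 1):
                sample = f"{lib}_{cond}_{rep}"
                s_j = float(rng.lognormal(0.0, config.library_factor_sigma))
                te = base_te * 2.0 ** (delta / 2 if cond == "case" else -delta / 2)
                mu = config.depth * expr * s_j * (te if lib == "ribo" else 1.0)
                cols[sample] = _nb_draw(rng, mu, config.dispersion)
                rows.append(
                    {"sample_id": sample, "library_type": lib,
                     "condition": cond, "replicate": rep, "library_factor": s_j}
                )
    ribo = pd.DataFrame(ribo_cols, index=genes)
    rna = pd.DataFrame(rna_cols, index=genes)
    sheet = pd.DataFrame(rows)
    return ribo, rna, sheet


_LENGTHS = np.arange(26, 35)
_LENGTH_PROBS = np.array([0.02, 0.05, 0.10, 0.22, 0.25, 0.15, 0.10, 0.07, 0.04])


def simulate_footprints(
    models: Mapping[str, UnionGeneModel],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "ribo_case_1",
) -> pd.DataFrame:
    """Transcript-space footprint records with planted positional structure.

    CDS midpoints sit at codon offsets with frame-0 probability
    ``periodicity_p`` (remaining mass split between frames 1 and 2); 5'UTR
    midpoints are uniform over the region reachable by realigned reads,
    except multiplied by ``depletion_factor`` inside the depletion window for
    flagged genes.  Lengths are drawn from 26-34 nt with a 29-30 nt mode, and
    5' ends are back-computed so midpoint realignment reproduces the drawn
    midpoint exactly.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 3])
    max_half = int(_LENGTHS.max()) // 2
    refs, mids, lens = [], [], []
    for g in truth.index:
        model = models[g]
        cds_start, cds_end = model.cds_start_tx, model.cds_end_tx
        n_codons = (cds_end - cds_start) // 3
        n_cds = rng.poisson(config.footprints_per_gene)
        if n_cds > 0 and n_codons > 1:
            codons = rng.integers(0, n_codons - 1, size=n_cds)
            p0 = config.periodicity_p
            frames = rng.choice(3, size=n_cds, p=[p0, (1 - p0) / 2, (1 - p0) / 2])
            cds_mids = cds_start + 3 * codons + frames
            refs.extend([g] * n_cds)
            mids.append(cds_mids)
            lens.append(rng.choice(_LENGTHS, size=n_cds, p=_LENGTH_PROBS))
        # 5'UTR reads: midpoints over [max_half, cds_start)
        if cds_start > max_half + 1:
            n_utr = rng.poisson(config.utr5_footprints_per_gene)
            if n_utr > 0:
                positions = np.arange(max_half, cds_start)
                weights = np.ones(positions.size)
                if bool(truth.at[g, "depleted"]):
                    lo = cds_start + config.depletion_window[0]
                    hi = cds_start + config.depletion_window[1]
                    in_win = (positions >= lo) & (positions <= hi)
                    weights[in_win] = config.depletion_factor
                weights /= weights.sum()
                utr_mids = rng.choice(positions, size=n_utr, p=weights)
                utr_lens = rng.choice(_LENGTHS, size=n_utr, p=_LENGTH_PROBS)
                # keep the 5' end on the transcript
                utr_lens = np.minimum(utr_lens, 2 * utr_mids)
                refs.extend([g] * n_utr)
                mids.append(utr_mids)
                lens.append(utr_lens)
    mids_arr = np.concatenate(mids) if mids else np.empty(0, dtype=int)
    lens_arr = np.concatenate(lens) if lens else np.empty(0, dtype=int)
    df = pd.DataFrame(
        {
            "reference": refs,
            "five_prime": mids_arr - lens_arr // 2,
            "length": lens_arr,
            "strand": "+",
            "sample_id": sample_id,
        }
    )
    return df[FOOTPRINT_COLUMNS]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all generator stages with seeds derived from ``config.seed``."""
    models, sequences, truth = simulate_transcriptome(config)
    structure, reactivity = simulate_structure(models, sequences, config, truth)
    ribo, rna, sheet = simulate_counts(models, truth, config)
    fps = simulate_footprints(models, truth, config)
    return SimulatedDataset(
        config=config, models=models, sequences=sequences, truth=truth,
        structure=structure, reactivity=reactivity, ribo=ribo, rna=rna,
        sample_sheet=sheet, footprints=fps,
    )


def truth_recovery_report(
    te_result: pd.DataFrame,
    truth: pd.DataFrame,
    energy_comparison: Optional[dict] = None,
    strata_tests: Optional[dict] = None,
    depletion_scores: Optional[pd.Series] = None,
) -> dict:
    """Compare pipeline outputs with the planted truth.

    Returns TE-classification sensitivity and false-positive rate, the mean
    measured delta TE per planted class, sign agreement of the strata
    medians, the energy-comparison p-value, and the depletion-score AUC
    (probability that a depleted gene scores below an unflagged one).
    """
    shared = te_result.index.intersection(truth.index)
    if len(shared) == 0:
        raise ValueError("gene universes of pipeline output and truth do not overlap")
    labels = te_result.loc[shared, "label"]
    planted = truth.loc[shared, "delta_te"]
    true_up = planted > 0
    true_down = planted < 0
    null = planted == 0
    metrics: dict = {
        "n_retained": int(len(shared)),
        "sensitivity_up": float((labels[true_up] == "up").mean()) if true_up.any() else None,
        "sensitivity_down": float((labels[true_down] == "down").mean()) if true_down.any() else None,
        "fpr_up": float((labels[null] == "up").mean()) if null.any() else None,
        "fpr_down": float((labels[null] == "down").mean()) if null.any() else None,
        "mean_delta_te_by_class": {
            cls: float(te_result.loc[shared[truth.loc[shared, "structure_class"] == cls], "delta_te"].mean())
            for cls in ("complex", "mid", "simple")
        },
    }
    if energy_comparison is not None:
        metrics["energy_comparison"] = {
            grp: {
                "p_value": res.mannwhitney.p_value,
                "group_median": res.group_median,
                "control_median": res.control_median,
            }
            for grp, res in energy_comparison.items()
        }
    if strata_tests is not None:
        metrics["strata"] = {
            name: {"median_delta_te": r.median_delta_te, "p_value": r.test.p_value, "n": r.n}
            for name, r in strata_tests.items()
        }
        med_c = strata_tests.get("complex")
        med_s = strata_tests.get("simple")
        if med_c and med_s:
            metrics["strata_sign_agreement"] = bool(
                np.sign(med_c.median_delta_te) != np.sign(med_s.median_delta_te)
                or med_s.median_delta_te == 0
            )
    if depletion_scores is not None:
        scores = depletion_scores.dropna()
        flagged = truth.loc[scores.index, "depleted"].astype(bool)
        pos = scores[flagged].to_numpy()
        neg = scores[~flagged].to_numpy()
        if pos.size and neg.size:
            # AUC: P(depleted gene scores lower) via pairwise comparison
            wins = (pos[:, None] < neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            metrics["depletion_auc"] = float(wins / (pos.size * neg.size))
    return metrics
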