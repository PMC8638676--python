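"""End-to-end analysis orchestration.

``analyze`` drives the in-memory flow (annotation -> footprint processing ->
expression -> structure analysis) and is the programmatic entry point;
``run_pipeline`` wraps it with file I/O and a provenance record for the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import io as rio
from .annotation import UnionGeneModel, load_gene_models, union_isoforms
from .expression import TESummary, te_analysis
from .footprints import (
    CountReport, DepletionResult, FilterReport, PeriodicityProfile,
    count_cds, depletion_score, min_count_filter, occupancy_profile,
    periodicity_profile, preprocess_footprints,
    KEEP_RANGE, MIN_COUNT, MIN_LENGTH,
)
from .structure import (
    COMPLEX_CUTOFF, SIMPLE_CUTOFF, group_energy_comparison,
    icshape_window_profile, strata_delta_te_test, stratify_by_energy,
    top_mrna_control,
)

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """All fixed analysis constants in one place."""

    min_len: int = MIN_LENGTH
    keep_range: tuple[int, int] = KEEP_RANGE
    min_count: int = MIN_COUNT
    z_cutoff: float = 1.5
    complex_cutoff: float = COMPLEX_CUTOFF
    simple_cutoff: float = SIMPLE_CUTOFF
    icshape_window: tuple[int, int] = (-100, 0)
    depletion_window: tuple[int, int] = (-20, -15)
    depletion_min_reads: int = 50
    n_permutations: int = 1000
    n_resample: int = 1
    seed: int = 0
    case: str = "case"
    control: str = "control"


@dataclass
class AnalysisResult:
    thresholds: Thresholds
    retained_genes: pd.Index
    te_table: pd.DataFrame
    te_summary: TESummary
    drop_log: dict
    energy_comparison: dict = field(default_factory=dict)
    utr3_energy_comparison: dict = field(default_factory=dict)
    strata_tests: dict = field(default_factory=dict)
    top_test: object = None
    icshape: object = None
    periodicity: Optional[PeriodicityProfile] = None
    depletion: Optional[pd.DataFrame] = None
    filter_report: Optional[FilterReport] = None
    count_report: Optional[CountReport] = None

    def summary_dict(self) -> dict:
        out = {
            "thresholds": asdict(self.thresholds),
            "n_retained": int(len(self.retained_genes)),
            "te_summary": self.te_summary.as_dict(),
            "drop_log": self.drop_log,
        }
        if self.energy_comparison:
            out["energy_comparison"] = {g: r.as_dict() for g, r in self.energy_comparison.items()}
        if self.utr3_energy_comparison:
            out["utr3_energy_comparison"] = {
                g: r.as_dict() for g, r in self.utr3_energy_comparison.items()
            }
        if self.strata_tests:
            out["strata_tests"] = {k: r.as_dict() for k, r in self.strata_tests.items()}
        if self.top_test is not None:
            out["top_test"] = self.top_test.as_dict()
        if self.periodicity is not None:
            out["periodicity"] = {
                "frame_fractions": self.periodicity.frame_fractions.tolist(),
                "n_reads": self.periodicity.n_reads,
                "undefined": self.periodicity.undefined,
            }
        if self.icshape is not None:
            out["icshape"] = {
                "window": list(self.icshape.window),
                "all_mean": self.icshape.all_mean,
                "groups": {
                    g: {
                        "n_genes": r.n_genes,
                        "window_mean": r.window_mean,
                        "p_value": r.test_vs_all.p_value if r.test_vs_all else None,
                    }
                    for g, r in self.icshape.groups.items()
                },
            }
        return out


def analyze(
    models: Mapping[str, UnionGeneModel],
    ribo: Optional[pd.DataFrame],
    rna: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    energies: Optional[pd.DataFrame] = None,
    reactivity: Optional[Mapping[str, np.ndarray]] = None,
    footprints: Optional[pd.DataFrame] = None,
    top_genes=None,
    thresholds: Optional[Thresholds] = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory inputs.

    ``ribo`` may be None when ``footprints`` are supplied, in which case the
    footprint count table is produced by midpoint-in-CDS counting.  The gene
    drop log records how many genes each filter removed, so
    (genes in) - (genes out) is always accounted for.
    """
    th = thresholds or Thresholds()
    drop_log: dict = {}
    filter_report = count_report = None
    clean_fps = None
    if footprints is not None:
        clean_fps, filter_report = preprocess_footprints(
            footprints, min_len=th.min_len, keep_range=th.keep_range
        )
        drop_log["footprint_filter"] = filter_report.as_dict()
    if ribo is None:
        if clean_fps is None:
            raise ValueError("need either a ribo count table or footprint records")
        ribo, count_report = count_cds(clean_fps, models)
        drop_log["cds_counting"] = count_report.as_dict()

    universe = ribo.index.union(rna.index)
    retained = min_count_filter(ribo, rna, threshold=th.min_count)
    drop_log["min_count_filter"] = {
        "genes_in": int(len(universe)),
        "genes_retained": int(len(retained)),
        "genes_dropped": int(len(universe) - len(retained)),
    }
    ribo_f = ribo.loc[retained]
    rna_f = rna.loc[retained]
    te_table, te_summary = te_analysis(
        ribo_f, rna_f, sample_sheet, case=th.case, control=th.control, z_cutoff=th.z_cutoff
    )
    dropped_te = len(retained) - len(te_table)
    drop_log["te_positivity"] = {"genes_dropped": int(dropped_te)}

    result = AnalysisResult(
        thresholds=th, retained_genes=te_table.index, te_table=te_table,
        te_summary=te_summary, drop_log=drop_log,
        filter_report=filter_report, count_report=count_report,
    )
    labels = te_table["label"]
    delta = te_table["delta_te"]

    if energies is not None:
        utr5 = energies["utr5_energy"].reindex(te_table.index).dropna()
        result.energy_comparison = group_energy_comparison(
            labels, utr5, rng_seed=th.seed, n_resample=th.n_resample
        )
        if "utr3_energy" in energies.columns:
            utr3 = energies["utr3_energy"].reindex(te_table.index).dropna()
            result.utr3_energy_comparison = group_energy_comparison(
                labels, utr3, rng_seed=th.seed + 1, n_resample=th.n_resample
            )
        complex_set, simple_set = stratify_by_energy(
            utr5, complex_cutoff=th.complex_cutoff, simple_cutoff=th.simple_cutoff
        )
        for name, stratum in (("complex", complex_set), ("simple", simple_set)):
            try:
                result.strata_tests[name] = strata_delta_te_test(stratum, delta, name=name)
            except ValueError as exc:
                logger.warning("stratum %s skipped: %s", name, exc)
    if top_genes is not None:
        try:
            result.top_test = top_mrna_control(delta, top_genes).test
        except ValueError as exc:
            logger.warning("5'TOP control skipped: %s", exc)
    if reactivity is not None:
        starts = {g: models[g].cds_start_tx for g in te_table.index if g in models}
        try:
            result.icshape = icshape_window_profile(
                labels, {g: v for g, v in reactivity.items() if g in starts},
                starts, window=th.icshape_window,
            )
        except ValueError as exc:
            logger.warning("icSHAPE window analysis skipped: %s", exc)

    if clean_fps is not None:
        result.periodicity = periodicity_profile(clean_fps, models)
        rows = []
        rng = np.random.default_rng(th.seed)
        by_ref = dict(tuple(clean_fps.groupby("reference", sort=False)))
        for g in te_table.index:
            model = models.get(g)
            if model is None or model.utr5_length < 40:
                continue
            gene_fps = by_ref.get(g)
            if gene_fps is None:
                continue
            prof = occupancy_profile(model, gene_fps)
            dep = depletion_score(
                prof, model.cds_start_tx, window=th.depletion_window,
                min_utr5_reads=th.depletion_min_reads,
                n_permutations=th.n_permutations, rng=rng,
            )
            rows.append(
                {"gene_id": g, "score": dep.score, "p_value": dep.p_value,
                 "n_utr5_reads": dep.n_utr5_reads, "reason": dep.reason}
            )
        if rows:
            result.depletion = pd.DataFrame(rows).set_index("gene_id")
    return result


@dataclass
class RunConfig:
    """File-based run configuration (CLI surface)."""

    annotation: str
    rna_counts: str
    sample_sheet: str
    outdir: str
    ribo_counts: Optional[str] = None
    footprints: Optional[str] = None
    energy_table: Optional[str] = None
    reactivity: Optional[str] = None
    top_genes: Optional[str] = None
    annotation_format: Optional[str] = None
    thresholds: Thresholds = field(default_factory=Thresholds)


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """Execute the pipeline from files and write the result bundle.

    Outputs under ``outdir``: te_results.tsv, summary.json (incl. drop log
    and provenance), depletion.tsv and periodicity_metagene.tsv when
    footprints were given.
    """
    with open(config.annotation) as fh:
        isoforms = load_gene_models(fh, fmt=config.annotation_format)
    models = union_isoforms(isoforms)
    rna = rio.read_counts(config.rna_counts)
    sheet = rio.read_sample_sheet(config.sample_sheet)
    ribo = rio.read_counts(config.ribo_counts) if config.ribo_counts else None
    fps = rio.read_footprints(config.footprints) if config.footprints else None
    if ribo is None and fps is None:
        raise ValueError("need --ribo-counts or --footprints")
    if fps is not None and len(fps) == 0:
        raise ValueError(f"footprint file {config.footprints} is empty")
    energies = rio.read_energy_table(config.energy_table) if config.energy_table else None
    reactivity = rio.read_reactivity_tsv(config.reactivity) if config.reactivity else None
    top = None
    if config.top_genes:
        top = [l.strip() for l in Path(config.top_genes).read_text().splitlines() if l.strip()]

    result = analyze(
        models, ribo, rna, sheet, energies=energies, reactivity=reactivity,
        footprints=fps, top_genes=top, thresholds=config.thresholds,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.te_table.to_csv(outdir / "te_results.tsv", sep="\t", index_label="gene_id")
    summary = result.summary_dict()
    summary["provenance"] = {
        "config": {k: v for k, v in asdict(config).items() if k != "thresholds"},
        "seed": config.thresholds.seed,
    }
    rio.write_json(summary, outdir / "summary.json")
    if result.depletion is not None:
        result.depletion.to_csv(outdir / "depletion.tsv", sep="\t", index_label="gene_id")
    if result.periodicity is not None:
        lo, hi = result.periodicity.window
        pd.DataFrame(
            {"position": np.arange(lo, hi + 1), "count": result.periodicity.metagene}
        ).to_csv(outdir / "periodicity_metagene.tsv", sep="\t", index=False)
    return result
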