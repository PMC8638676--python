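"""Expression normalization, translation efficiency and z-score classification.

Translation efficiency (TE) is the ratio of a gene's normalized ribosome
footprint abundance to its normalized mRNA abundance.  Counts are normalized
with median-of-ratios size factors (the normalization underlying
negative-binomial differential-expression frameworks); the full NB-GLM with
dispersion shrinkage is deliberately not reimplemented, because the
classification here is an empirical z score on per-gene log2 TE differences
rather than a per-gene Wald test.

delta TE = log2 TE(case) - log2 TE(control); genes with |z| >= cutoff
(default 1.5, inclusive) are labelled TE-up / TE-down.  All logs are base 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

Z_CUTOFF = 1.5


class NormalizationError(ValueError):
    pass


def size_factors(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    The per-gene reference is the geometric mean of that gene's counts across
    samples (genes with any zero count are excluded from the reference set);
    each sample's factor is the median over genes of count / reference.
    """
    counts = table.to_numpy(dtype=float)
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; pre-filter the table"
        )
    log_counts = np.log(counts[nonzero])
    ref = np.exp(log_counts.mean(axis=1, keepdims=True))
    factors = np.median(counts[nonzero] / ref, axis=0)
    return pd.Series(factors, index=table.columns, name="size_factor")


def normalized_condition_means(
    table: pd.DataFrame,
    factors: pd.Series,
    condition_map: Mapping[str, str],
) -> pd.DataFrame:
    """Mean normalized count (count / factor) per gene per condition."""
    conditions = sorted(set(condition_map.values()))
    missing = [s for s in table.columns if s not in condition_map]
    if missing:
        raise ValueError(f"samples without a condition: {missing}")
    normalized = table.div(factors, axis=1)
    out = {}
    for cond in conditions:
        cols = [s for s in table.columns if condition_map[s] == cond]
        if not cols:
            raise ValueError(f"condition {cond!r} has zero samples")
        out[cond] = normalized[cols].mean(axis=1)
    return pd.DataFrame(out)


def translation_efficiency(
    ribo_means: pd.DataFrame, rna_means: pd.DataFrame
) -> pd.DataFrame:
    """TE = normalized footprint mean / normalized mRNA mean, per condition.

    Genes with a zero ribosome or mRNA mean in any condition are dropped
    (TE undefined); the caller's count filter normally prevents this.
    """
    shared = ribo_means.index.intersection(rna_means.index)
    ribo = ribo_means.loc[shared]
    rna = rna_means.loc[shared]
    ok = (ribo > 0).all(axis=1) & (rna > 0).all(axis=1)
    return (ribo[ok] / rna[ok]).dropna()


@dataclass
class TESummary:
    n_genes: int
    mean_delta_te: float
    sd_delta_te: float
    z_cutoff: float
    n_up: int
    n_down: int
    n_neutral: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def classify_delta_te(
    delta_te: pd.Series, z_cutoff: float = Z_CUTOFF
) -> tuple[pd.DataFrame, TESummary]:
    """Standard z score of log2 delta TE and the +/- cutoff classification.

    z = (delta - mean) / SD with the sample (n-1) standard deviation; labels
    are 'up' iff z >= +cutoff, 'down' iff z <= -cutoff, else 'neutral'
    (inclusive cutoffs).  The summary reports the SD of the TE differences.
    """
    values = delta_te.to_numpy(dtype=float)
    if len(values) < 3:
        raise ValueError("need >= 3 genes to classify")
    if not np.isfinite(values).all():
        raise ValueError("delta_te contains non-finite values")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        z = np.zeros_like(values)
    else:
        z = (values - mean) / sd
    label = np.where(z >= z_cutoff, "up", np.where(z <= -z_cutoff, "down", "neutral"))
    result = pd.DataFrame({"delta_te": values, "z": z, "label": label}, index=delta_te.index)
    summary = TESummary(
        n_genes=len(values), mean_delta_te=float(mean), sd_delta_te=float(sd),
        z_cutoff=z_cutoff, n_up=int((label == "up").sum()),
        n_down=int((label == "down").sum()), n_neutral=int((label == "neutral").sum()),
    )
    return result, summary


def te_analysis(
    ribo: pd.DataFrame,
    rna: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    case: str,
    control: str,
    z_cutoff: float = Z_CUTOFF,
) -> tuple[pd.DataFrame, TESummary]:
    """End-to-end TE table for one case/control contrast.

    ``sample_sheet`` needs columns sample_id, library_type ('ribo'/'rna') and
    condition.  Count tables are expected to be pre-filtered (low-count genes
    removed).  Returns a per-gene frame with normalized condition means, TE
    per condition, delta_te, z and label, plus the classification summary.
    """
    cond = dict(zip(sample_sheet["sample_id"], sample_sheet["condition"]))
    ribo_means = normalized_condition_means(ribo, size_factors(ribo), cond)
    rna_means = normalized_condition_means(rna, size_factors(rna), cond)
    te = translation_efficiency(ribo_means, rna_means)
    delta = np.log2(te[case]) - np.log2(te[control])
    classified, summary = classify_delta_te(delta, z_cutoff)
    out = pd.DataFrame(index=te.index)
    for c in (case, control):
        out[f"norm_ribo_{c}"] = ribo_means.loc[te.index, c]
        out[f"norm_rna_{c}"] = rna_means.loc[te.index, c]
        out[f"te_{c}"] = te[c]
    out["delta_te"] = classified["delta_te"]
    out["z"] = classified["z"]
    out["label"] = classified["label"]
    return out, summary


def replicate_concordance(te_a: pd.Series, te_b: pd.Series) -> float:
    """Spearman rank correlation of per-gene TE between two replicates."""
    shared = te_a.index.intersection(te_b.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need >= 10")
    rho, _ = sps.spearmanr(te_a.loc[shared], te_b.loc[shared])
    return float(rho)
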