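import numpy as np
import pandas as pd
import pytest

from ribostruct.expression import (
    NormalizationError, classify_delta_te, normalized_condition_means,
    replicate_concordance, size_factors, te_analysis, translation_efficiency,
)
from ribostruct.synthetic import SimulationConfig, simulate_dataset

from oracles import bruteforce_size_factors


def frame(rows, samples):
    return pd.DataFrame(rows, columns=samples, index=[f"g{i}" for i in range(len(rows))])


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        t = frame([[10, 10], [50, 50]], ["a", "b"])
        assert np.allclose(size_factors(t), [1, 1])

    def test_doubled_sample_gets_doubled_factor(self):
        t = frame([[10, 20], [50, 100], [7, 14]], ["a", "b"])
        f = size_factors(t)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_hand_computed_example(self):
        # every gene's ratio pair is (1/sqrt(2), sqrt(2))
        t = frame([[10, 20], [100, 200], [1000, 2000]], ["a", "b"])
        f = size_factors(t)
        assert np.allclose(f, [2 ** -0.5, 2 ** 0.5])

    def test_all_zero_gene_rows_raise(self):
        t = frame([[0, 10], [5, 0]], ["a", "b"])
        with pytest.raises(NormalizationError, match="pre-filter"):
            size_factors(t)

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            counts = rng.negative_binomial(5, 0.05, size=(30, 4)).astype(float)
            counts[0] += 1  # guarantee one all-nonzero gene
            t = frame(counts, [f"s{j}" for j in range(4)])
            assert np.allclose(size_factors(t), bruteforce_size_factors(counts), atol=1e-12)


class TestNormalizedMeans:
    def test_single_replicate_identity(self):
        t = frame([[10]], ["a"])
        out = normalized_condition_means(t, pd.Series({"a": 1.0}), {"a": "c1"})
        assert out.loc["g0", "c1"] == 10

    def test_mean_across_replicates(self):
        t = frame([[10, 30]], ["a", "b"])
        out = normalized_condition_means(
            t, pd.Series({"a": 1.0, "b": 1.0}), {"a": "c", "b": "c"}
        )
        assert out.loc["g0", "c"] == 20

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        t = frame(rng.integers(1, 100, (5, 4)), list("abcd"))
        factors = pd.Series(rng.uniform(0.5, 2, 4), index=list("abcd"))
        cond = {"a": "x", "b": "x", "c": "y", "d": "y"}
        out = normalized_condition_means(t, factors, cond)
        for g in t.index:
            for c, cols in (("x", "ab"), ("y", "cd")):
                expected = np.mean([t.loc[g, s] / factors[s] for s in cols])
                assert out.loc[g, c] == pytest.approx(expected)

    def test_missing_condition_errors(self):
        t = frame([[1, 2]], ["a", "b"])
        with pytest.raises(ValueError):
            normalized_condition_means(t, pd.Series({"a": 1.0, "b": 1.0}), {"a": "x"})


class TestTranslationEfficiency:
    def test_simple_ratios(self):
        ribo = pd.DataFrame({"c": [100.0, 300.0]}, index=["g1", "g2"])
        rna = pd.DataFrame({"c": [100.0, 100.0]}, index=["g1", "g2"])
        te = translation_efficiency(ribo, rna)
        assert te.loc["g1", "c"] == 1.0 and te.loc["g2", "c"] == 3.0

    def test_zero_means_dropped(self):
        ribo = pd.DataFrame({"c": [0.0, 300.0]}, index=["g1", "g2"])
        rna = pd.DataFrame({"c": [100.0, 100.0]}, index=["g1", "g2"])
        assert list(translation_efficiency(ribo, rna).index) == ["g2"]


class TestClassifyDeltaTe:
    def test_hand_example_inclusive_cutoff(self):
        # (0,0,0,3): mean 0.75, sample SD 1.5, so z(3) = 1.5 exactly -> 'up'
        delta = pd.Series([0.0, 0.0, 0.0, 3.0], index=list("abcd"))
        result, summary = classify_delta_te(delta)
        assert summary.sd_delta_te == pytest.approx(1.5)
        assert result.loc["d", "z"] == pytest.approx(1.5)
        assert result.loc["d", "label"] == "up"
        assert (result.loc[list("abc"), "label"] == "neutral").all()

    def test_constant_vector_all_neutral(self):
        delta = pd.Series([1.0, 1.0, 1.0])
        result, summary = classify_delta_te(delta)
        assert (result["label"] == "neutral").all()
        assert summary.sd_delta_te == 0.0

    def test_normal_sample_tail_fraction(self):
        rng = np.random.default_rng(10)
        delta = pd.Series(rng.normal(0, 1, 10000))
        _, summary = classify_delta_te(delta)
        expected = 1 - 0.9331927  # 1 - Phi(1.5)
        assert abs(summary.n_up / summary.n_genes - expected) < 0.01
        assert abs(summary.n_down / summary.n_genes - expected) < 0.01

    def test_label_partition(self):
        rng = np.random.default_rng(11)
        _, summary = classify_delta_te(pd.Series(rng.normal(0, 1, 500)))
        assert summary.n_up + summary.n_down + summary.n_neutral == summary.n_genes


@pytest.fixture(scope="module")
def te_inputs():
    ds = simulate_dataset(SimulationConfig(n_genes=400, seed=21))
    return ds.ribo, ds.rna, ds.sample_sheet


class TestPipelineInvariances:
    def test_case_control_antisymmetry(self, te_inputs):
        ribo, rna, sheet = te_inputs
        fwd, _ = te_analysis(ribo, rna, sheet, case="case", control="control")
        swapped = sheet.copy()
        swapped["condition"] = swapped["condition"].map(
            {"case": "control", "control": "case"}
        )
        rev, _ = te_analysis(ribo, rna, swapped, case="case", control="control")
        assert np.allclose(fwd["delta_te"], -rev["delta_te"])
        assert set(fwd.index[fwd["label"] == "up"]) == set(rev.index[rev["label"] == "down"])
        assert set(fwd.index[fwd["label"] == "down"]) == set(rev.index[rev["label"] == "up"])

    def test_single_sample_rescaling_preserves_delta_and_labels(self, te_inputs):
        """Scaling one library's counts is absorbed into normalization:
        delta_te and labels are exactly invariant (TE shifts by a common
        factor that cancels between conditions)."""
        ribo, rna, sheet = te_inputs
        base, _ = te_analysis(ribo, rna, sheet, case="case", control="control")
        scaled = ribo.copy()
        scaled["ribo_case_1"] = scaled["ribo_case_1"] * 3
        out, _ = te_analysis(scaled, rna, sheet, case="case", control="control")
        assert np.allclose(base["delta_te"], out["delta_te"])
        assert (base["label"] == out["label"]).all()
        ratio = out["te_case"] / base["te_case"]
        assert np.allclose(ratio, ratio.iloc[0])  # common factor only

    def test_doubling_rna_counts_preserves_delta(self, te_inputs):
        ribo, rna, sheet = te_inputs
        base, _ = te_analysis(ribo, rna, sheet, case="case", control="control")
        out, _ = te_analysis(ribo, rna * 2, sheet, case="case", control="control")
        assert np.allclose(base["delta_te"], out["delta_te"])
        assert (base["label"] == out["label"]).all()


class TestReplicateConcordance:
    def test_identical_and_reversed(self):
        te = pd.Series(np.arange(20, dtype=float), index=[f"g{i}" for i in range(20)])
        assert replicate_concordance(te, te) == pytest.approx(1.0)
        assert replicate_concordance(te, te.iloc[::-1].set_axis(te.index)) == pytest.approx(-1.0)

    def test_too_few_shared_genes(self):
        te = pd.Series([1.0] * 5, index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="need >= 10"):
            replicate_concordance(te, te)

    def test_replicates_from_same_truth_are_concordant(self, te_inputs):
        """Two replicates of the same condition rank genes consistently
        (dispersion 0.05, depth ~400), assessed on the analysis gene set."""
        from ribostruct.footprints import min_count_filter

        ribo, rna, sheet = te_inputs
        kept = min_count_filter(ribo, rna)
        ribo, rna = ribo.loc[kept], rna.loc[kept]
        f_ribo = size_factors(ribo)
        f_rna = size_factors(rna)
        te_a = (ribo["ribo_control_1"] / f_ribo["ribo_control_1"]) / (
            rna["rna_control_1"] / f_rna["rna_control_1"]
        )
        te_b = (ribo["ribo_control_2"] / f_ribo["ribo_control_2"]) / (
            rna["rna_control_2"] / f_rna["rna_control_2"]
        )
        ok = np.isfinite(te_a) & np.isfinite(te_b) & (te_a > 0) & (te_b > 0)
        rho = replicate_concordance(te_a[ok], te_b[ok])
        assert rho >= 0.8
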