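import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ribostruct.annotation import UnionGeneModel
from ribostruct.footprints import (
    OccupancyProfile, count_cds, depletion_score, midpoint_realign,
    min_count_filter, occupancy_profile, periodicity_profile,
    preprocess_footprints,
)

from conftest import make_footprints


class TestPreprocess:
    def test_length_window_boundaries(self):
        fps = make_footprints([("g", 0, l) for l in (24, 25, 26, 34, 35)])
        kept, report = preprocess_footprints(fps)
        assert sorted(kept["length"]) == [26, 34]
        assert report.below_min_length == 1  # the 24 nt read
        assert report.outside_keep_range == 2  # 25 and 35 nt
        assert report.kept == 2

    def test_empty_input(self):
        kept, report = preprocess_footprints(make_footprints([]))
        assert len(kept) == 0
        assert report.as_dict() == dict(
            total=0, invalid_length=0, below_min_length=0, outside_keep_range=0, kept=0
        )

    def test_negative_length_rejected_and_counted(self):
        fps = make_footprints([("g", 0, -3), ("g", 0, 30)])
        kept, report = preprocess_footprints(fps)
        assert report.invalid_length == 1
        assert len(kept) == 1

    def test_bulk_filter_matches_exhaustive_recount(self):
        rng = np.random.default_rng(0)
        lengths = rng.integers(20, 41, size=1000)
        fps = make_footprints([("g", 0, int(l)) for l in lengths])
        kept, report = preprocess_footprints(fps)
        expected = sum(1 for l in lengths if 26 <= l <= 34)
        assert report.kept == len(kept) == expected
        assert report.total == report.invalid_length + report.below_min_length \
            + report.outside_keep_range + report.kept


class TestMidpointRealign:
    @pytest.mark.parametrize(
        "fp,length,strand,expected",
        [
            (100, 30, "+", 115),   # 5' end + floor(length/2)
            (100, 29, "+", 114),   # floor rounding for odd lengths
            (0, 26, "+", 13),
            (100, 30, "-", 85),    # strand-aware in genomic space
        ],
    )
    def test_scalar(self, fp, length, strand, expected):
        assert midpoint_realign(fp, length, strand) == expected

    def test_vectorized_matches_scalar(self):
        fp = np.array([0, 10, 100])
        ln = np.array([26, 29, 34])
        strands = np.array(["+", "-", "+"])
        out = midpoint_realign(fp, ln, strands)
        assert list(out) == [midpoint_realign(int(f), int(l), s)
                             for f, l, s in zip(fp, ln, strands)]


def tx_model(gene, utr5, cds, utr3):
    total = utr5 + cds + utr3
    return UnionGeneModel(gene, gene, "+", ((0, total),), ((utr5, utr5 + cds),))


class TestCountCds:
    def test_midpoint_membership_and_boundary(self):
        model = tx_model("g", 100, 100, 50)  # CDS tx [100,200)
        fps = make_footprints([
            ("g", 135, 30),  # midpoint 150 -> in CDS
            ("g", 35, 30),   # midpoint 50 -> 5'UTR
            ("g", 185, 30),  # midpoint 200 -> exactly at half-open end
        ])
        counts, report = count_cds(fps, {"g": model})
        assert counts.at["g", "s1"] == 1
        assert report.outside_cds["s1"] == 2

    def test_unknown_reference_logged(self):
        model = tx_model("g", 50, 90, 40)
        fps = make_footprints([("nope", 60, 30)])
        counts, report = count_cds(fps, {"g": model})
        assert counts["s1"].sum() == 0
        assert report.unknown_reference["s1"] == 1

    def test_random_midpoints_match_bruteforce(self):
        model = tx_model("g", 100, 300, 100)
        rng = np.random.default_rng(1)
        fp = rng.integers(0, 460, size=500)
        ln = rng.integers(26, 35, size=500)
        fps = make_footprints([("g", int(f), int(l)) for f, l in zip(fp, ln)])
        counts, _ = count_cds(fps, {"g": model})
        expected = sum(1 for f, l in zip(fp, ln) if 100 <= f + l // 2 < 400)
        assert counts.at["g", "s1"] == expected

    def test_genomic_ambiguous_midpoint_discarded(self):
        a = UnionGeneModel("a", "chr1", "+", ((0, 200),), ((50, 150),))
        b = UnionGeneModel("b", "chr1", "+", ((0, 200),), ((100, 180),))
        fps = make_footprints([
            ("chr1", 105, 30),  # midpoint 120: in both CDS -> ambiguous
            ("chr1", 45, 30),   # midpoint 60: only gene a
            ("chr1", 145, 30),  # midpoint 160: only gene b
        ])
        counts, report = count_cds(fps, {"a": a, "b": b}, space="genomic")
        assert counts.at["a", "s1"] == 1
        assert counts.at["b", "s1"] == 1
        assert report.ambiguous["s1"] == 1

    def test_rna_mode_any_overlap(self):
        a = UnionGeneModel("a", "chr1", "+", ((0, 200),), ((50, 150),))
        fps = make_footprints([
            ("chr1", 30, 30),   # spans [30,60): overlaps CDS start
            ("chr1", 10, 30),   # spans [10,40): no CDS overlap
        ])
        counts, _ = count_cds(fps, {"a": a}, rna_mode=True, space="genomic")
        assert counts.at["a", "s1"] == 1
        # footprint mode counts neither (midpoints 45 and 25)
        counts_fp, _ = count_cds(fps, {"a": a}, space="genomic")
        assert counts_fp.at["a", "s1"] == 0

    def test_minus_strand_genomic_midpoint(self):
        a = UnionGeneModel("a", "chr1", "-", ((0, 200),), ((50, 150),))
        # 5' end at genomic 160 on '-', length 30 -> midpoint 145 (in CDS)
        fps = make_footprints([("chr1", 160, 30, "-")])
        counts, _ = count_cds(fps, {"a": a}, space="genomic")
        assert counts.at["a", "s1"] == 1

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_count_conservation(self, data):
        """assigned + ambiguous + outside + unknown == total, any input."""
        models = {
            "a": UnionGeneModel("a", "chr1", "+", ((0, 300),), ((50, 200),)),
            "b": UnionGeneModel("b", "chr1", "+", ((100, 400),), ((150, 350),)),
        }
        n = data.draw(st.integers(0, 60))
        rows = [
            (data.draw(st.sampled_from(["chr1", "chrX"])),
             data.draw(st.integers(0, 450)), data.draw(st.integers(26, 34)))
            for _ in range(n)
        ]
        fps = make_footprints(rows)
        rna = data.draw(st.booleans())
        counts, rep = count_cds(fps, models, rna_mode=rna, space="genomic")
        if n:
            s = "s1"
            assert rep.assigned[s] + rep.ambiguous[s] + rep.outside_cds[s] \
                + rep.unknown_reference[s] == rep.total[s] == n
            assert counts[s].sum() == rep.assigned[s]

    def test_shift_equivariance(self):
        """Translating footprints and models together leaves counts unchanged."""
        shift = 1000
        a = UnionGeneModel("a", "chr1", "+", ((0, 300),), ((50, 200),))
        a2 = UnionGeneModel("a", "chr1", "+", ((shift, 300 + shift),), ((50 + shift, 200 + shift),))
        rng = np.random.default_rng(3)
        rows = [("chr1", int(p), int(l)) for p, l in
                zip(rng.integers(0, 280, 200), rng.integers(26, 35, 200))]
        fps = make_footprints(rows)
        fps2 = fps.assign(five_prime=fps["five_prime"] + shift)
        c1, _ = count_cds(fps, {"a": a}, space="genomic")
        c2, _ = count_cds(fps2, {"a": a2}, space="genomic")
        assert c1.equals(c2)


class TestMinCountFilter:
    def test_strict_128_boundary(self):
        ribo = pd.DataFrame({"s1": [127, 128], "s2": [0, 0]}, index=["g1", "g2"])
        rna = pd.DataFrame({"s1": [500, 128]}, index=["g1", "g2"])
        kept = min_count_filter(ribo, rna)
        assert list(kept) == ["g2"]

    def test_random_table_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        ribo = pd.DataFrame(rng.integers(0, 200, (20, 3)), index=genes)
        rna = pd.DataFrame(rng.integers(0, 200, (20, 3)), index=genes)
        kept = set(min_count_filter(ribo, rna))
        expected = {
            g for g in genes
            if ribo.loc[g].sum() >= 128 and rna.loc[g].sum() >= 128
        }
        assert kept == expected


class TestPeriodicity:
    def test_pure_frames(self):
        model = tx_model("g", 60, 300, 30)
        # all midpoints at frame 0 (positions 60, 63, 66)
        fps = make_footprints([("g", p - 15, 30) for p in (60, 63, 66)])
        prof = periodicity_profile(fps, {"g": model})
        assert np.allclose(prof.frame_fractions, [1, 0, 0])

    def test_uniform_frames(self):
        model = tx_model("g", 60, 300, 30)
        fps = make_footprints([("g", p - 15, 30) for p in (60, 61, 62)])
        prof = periodicity_profile(fps, {"g": model})
        assert np.allclose(prof.frame_fractions, [1 / 3] * 3)
        assert prof.frame_fractions.sum() == pytest.approx(1.0)

    def test_no_reads_flags_undefined(self):
        model = tx_model("g", 60, 300, 30)
        prof = periodicity_profile(make_footprints([]), {"g": model})
        assert prof.undefined and np.isnan(prof.frame_fractions).all()

    def test_metagene_window_sums(self):
        model = tx_model("g", 60, 300, 30)
        fps = make_footprints([("g", 60 - 15, 30)] * 4)  # midpoint at CDS start
        prof = periodicity_profile(fps, {"g": model}, window=(-20, 200))
        assert prof.metagene[20] == 4  # relative position 0
        assert prof.metagene.sum() == 4


class TestOccupancyAndDepletion:
    def test_occupancy_tally(self):
        model = tx_model("g", 60, 90, 30)
        fps = make_footprints([("g", 7, 26)] * 3)  # midpoint 20
        prof = occupancy_profile(model, fps)
        assert prof.values[20] == 3 and prof.values.sum() == 3

    def test_occupancy_matches_bincount(self):
        model = tx_model("g", 100, 200, 50)
        rng = np.random.default_rng(5)
        fp = rng.integers(0, 300, 1000)
        fps = make_footprints([("g", int(f), 30) for f in fp])
        prof = occupancy_profile(model, fps)
        mids = fp + 15
        for t in rng.integers(0, 350, 30):
            assert prof.values[t] == (mids == t).sum()

    def test_uniform_coverage_scores_one(self):
        values = np.full(400, 5.0)
        prof = OccupancyProfile("g", values)
        res = depletion_score(prof, cds_start_tx=300, n_permutations=50)
        assert res.score == pytest.approx(1.0)

    def test_zero_window_scores_zero(self):
        values = np.full(400, 5.0)
        values[280:286] = 0  # window [-20,-15] of cds_start 300
        prof = OccupancyProfile("g", values)
        res = depletion_score(prof, cds_start_tx=300, n_permutations=200, seed=1)
        assert res.score == 0.0
        assert res.p_value < 0.05

    def test_insufficient_reads_returns_reason(self):
        prof = OccupancyProfile("g", np.zeros(200))
        res = depletion_score(prof, cds_start_tx=100)
        assert res.score is None and "5'UTR reads" in res.reason

    def test_short_utr_rejected(self):
        prof = OccupancyProfile("g", np.full(100, 10.0))
        res = depletion_score(prof, cds_start_tx=30)
        assert res.score is None and "shorter" in res.reason

    def test_suppressed_window_scores_low(self):
        """Window coverage at 10% of background -> score near 0.1."""
        rng = np.random.default_rng(6)
        cds_start = 150
        weights = np.ones(cds_start - 17)
        weights[150 - 20 - 17 : 150 - 14 - 17] = 0.1
        positions = rng.choice(
            np.arange(17, cds_start), size=2000, p=weights / weights.sum()
        )
        values = np.zeros(300)
        np.add.at(values, positions, 1)
        res = depletion_score(OccupancyProfile("g", values), cds_start, seed=2)
        assert res.score <= 0.2
        assert res.p_value < 0.01
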