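"""Per-origin quantification, V plots, directionality, top-fraction sets."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mcmkit.chipquant import (
    density_profile,
    directional_split,
    inter_origin_distances,
    moving_average_by_rank,
    percent_signal_lost,
    quantify_origin_signal,
    top_fraction_origins,
    vplot,
)
from mcmkit.coverage import CoverageTrack
from mcmkit.fragments import make_fragment_frame

from conftest import build_origins


def track_from(values, bw=25):
    return CoverageTrack(bin_width=bw, data={"chr1": np.asarray(values, float)},
                         state="input_subtracted")


def fragment_at(midpoint, length, chrom="chr1"):
    start = midpoint - length // 2
    return make_fragment_frame([chrom], [start], [start + length], "chip")


class TestQuantifyOriginSignal:
    def test_zero_track_zero_signals(self):
        origins = build_origins([{"midpoint": 5_000, "acs": 5_000}])
        out = quantify_origin_signal(track_from(np.zeros(400)), origins)
        assert out["signal"].eq(0).all() and out["valid"].all()

    def test_delta_bin_at_midpoint(self):
        vals = np.zeros(400)
        vals[200] = 4.0
        origins = build_origins([{"midpoint": 5_000, "acs": 5_000}])
        out = quantify_origin_signal(track_from(vals), origins)
        assert out["signal"].iloc[0] == pytest.approx(4.0)

    def test_window_overhang_flagged_invalid(self):
        origins = build_origins([{"midpoint": 300, "acs": 300}])
        out = quantify_origin_signal(track_from(np.ones(400)), origins)
        assert not out["valid"].iloc[0]
        assert np.isnan(out["signal"].iloc[0])

    def test_matches_brute_force_window_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            vals = rng.normal(size=400)
            mid = int(rng.integers(600, 9_400))
            origins = build_origins([{"midpoint": mid, "acs": mid}])
            out = quantify_origin_signal(track_from(vals), origins)
            oracle = sum(
                v
                for i, v in enumerate(vals)
                if mid - 500 <= i * 25 + 12.5 < mid + 500
            )
            assert out["signal"].iloc[0] == pytest.approx(oracle)


class TestPercentSignalLost:
    def make_signals(self, values):
        return pd.DataFrame(
            {"name": [f"ori{i}" for i in range(len(values))],
             "signal": values, "valid": True}
        )

    def test_arithmetic(self):
        control = self.make_signals([8.0, 4.0, 2.0])
        treated = self.make_signals([2.0, 4.0, 0.0])
        out = percent_signal_lost(control, treated)
        assert dict(zip(out["name"], out["percent_lost"])) == pytest.approx(
            {"ori0": 75.0, "ori1": 0.0, "ori2": 100.0}
        )

    def test_nonpositive_control_filtered(self):
        control = self.make_signals([5.0, 0.0, -1.0])
        treated = self.make_signals([5.0, 1.0, 1.0])
        out = percent_signal_lost(control, treated)
        assert list(out["name"]) == ["ori0"]

    def test_quartiles_rank_by_loss(self):
        control = self.make_signals([10.0] * 8)
        treated = self.make_signals([10, 9, 8, 7, 6, 5, 4, 3.0])
        out = percent_signal_lost(control, treated)
        assert list(out["quartile"]) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]


class TestMovingAverage:
    def frame(self, p, key=None):
        return pd.DataFrame(
            {"name": [f"o{i}" for i in range(len(p))],
             "control": key if key is not None else np.arange(len(p)),
             "percent_lost": p}
        )

    def test_window_one_is_identity(self):
        out = moving_average_by_rank(self.frame([5.0, 1.0, 3.0]), window=1)
        np.testing.assert_allclose(out["smoothed"], [5.0, 1.0, 3.0])

    def test_constant_stays_constant(self):
        out = moving_average_by_rank(self.frame([2.0] * 10), window=5)
        np.testing.assert_allclose(out["smoothed"], 2.0)

    def test_window_three_center(self):
        out = moving_average_by_rank(self.frame([0.0, 30.0, 60.0]), window=3)
        assert out["smoothed"].iloc[1] == pytest.approx(30.0)


class TestVPlot:
    def test_empty_matrix(self):
        origins = build_origins([{"midpoint": 5_000, "acs": 5_000}])
        from mcmkit.fragments import empty_fragment_frame

        mat = vplot(empty_fragment_frame(), origins)
        assert mat.total == 0

    def test_single_fragment_at_plus_acs(self):
        origins = build_origins([{"midpoint": 5_000, "acs": 5_000, "strand": "+"}])
        mat = vplot(fragment_at(5_000, 68), origins)
        assert mat.total == 1
        assert mat.counts[350, 67] == 1  # offset 0, length 68

    def test_minus_strand_negates_offset(self):
        origins = build_origins([{"midpoint": 5_000, "acs": 5_000, "strand": "-"}])
        mat = vplot(fragment_at(5_010, 68), origins)
        assert mat.counts[350 - 10, 67] == 1

    def test_total_counts_anchored_fragments(self):
        rng = np.random.default_rng(3)
        origins = build_origins([{"midpoint": 5_000, "acs": 5_000}])
        mids = rng.integers(4_000, 6_000, size=300)
        lens = rng.integers(40, 700, size=300)
        frags = make_fragment_frame(
            ["chr1"] * 300, mids - lens // 2, mids - lens // 2 + lens, "chip"
        )
        frags = frags[frags["length"] <= 650].reset_index(drop=True)
        mat = vplot(frags, origins)
        recomputed_mids = (frags["start"] + frags["end"]) // 2
        expected = (
            (recomputed_mids - 5_000).abs().lt(350)
            | (recomputed_mids - 5_000).eq(-350)
        ).sum()
        assert mat.total == expected

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(11)
        origins = build_origins(
            [
                {"midpoint": 3_000, "acs": 3_010, "strand": "+"},
                {"midpoint": 7_000, "acs": 6_990, "strand": "-"},
            ]
        )
        mids = rng.integers(2_500, 7_500, size=200)
        lens = rng.integers(30, 200, size=200)
        frags = make_fragment_frame(
            ["chr1"] * 200, mids - lens // 2, mids - lens // 2 + lens, "chip"
        )
        mat = vplot(frags, origins, window=700, max_length=650)
        oracle = np.zeros_like(mat.counts)
        for _, frag in frags.iterrows():
            fmid = (frag["start"] + frag["end"]) // 2
            for _, ori in origins.iterrows():
                off = fmid - ori["acs"]
                if ori["strand"] == "-":
                    off = -off
                if -350 <= off < 350 and 1 <= frag["length"] <= 650:
                    oracle[off + 350, frag["length"] - 1] += 1
        np.testing.assert_array_equal(mat.counts, oracle)


class TestDensityProfile:
    def test_length_classes_partition_total(self, small_genome, two_origins):
        from mcmkit.simulate import sample_chip_fragments

        frags = sample_chip_fragments(two_origins, small_genome, 5_000,
                                      background_fraction=0.1, seed=13)
        full = density_profile(frags, two_origins)
        mcm = density_profile(frags, two_origins, length_class=(50, 90))
        nuc = density_profile(frags, two_origins, length_class=(125, 165))
        other_lo = density_profile(frags, two_origins, length_class=(1, 49))
        other_mid = density_profile(frags, two_origins, length_class=(91, 124))
        other_hi = density_profile(frags, two_origins, length_class=(166, 650))
        total = (mcm["density"] + nuc["density"] + other_lo["density"]
                 + other_mid["density"] + other_hi["density"])
        np.testing.assert_allclose(full["density"], total)

    def test_empty_class_zero_profile(self, small_genome, two_origins):
        from mcmkit.simulate import sample_chip_fragments

        frags = sample_chip_fragments(two_origins, small_genome, 2_000,
                                      digestion_level=0.0,
                                      background_fraction=0.0, seed=1)
        mcm = density_profile(frags, two_origins, length_class=(50, 90))
        assert not mcm["density"].any()

    def test_mirrored_strands_flip_profile(self, small_genome, two_origins):
        from mcmkit.simulate import sample_chip_fragments

        frags = sample_chip_fragments(two_origins, small_genome, 3_000,
                                      background_fraction=0.0, seed=21)
        flipped = two_origins.assign(
            strand=two_origins["strand"].map({"+": "-", "-": "+"})
        )
        prof = density_profile(frags, two_origins)["density"].to_numpy()
        prof_flipped = density_profile(frags, flipped)["density"].to_numpy()
        np.testing.assert_allclose(prof[1:], prof_flipped[1:][::-1])


class TestDirectionalSplit:
    def test_symmetric_signal_ties_to_upstream(self):
        origins = build_origins([{"midpoint": 5_000, "acs": 5_000}])
        out = directional_split(track_from(np.ones(400)), origins)
        assert out["tie"].iloc[0] and out["dominant"].iloc[0] == "upstream"

    def test_downstream_dominant_plus_strand(self):
        vals = np.zeros(400)
        vals[(5_000 + 200) // 25] = 5.0
        origins = build_origins([{"midpoint": 5_000, "acs": 5_000, "strand": "+"}])
        out = directional_split(track_from(vals), origins)
        assert out["dominant"].iloc[0] == "downstream"

    def test_minus_strand_swaps_sides(self):
        vals = np.zeros(400)
        vals[(5_000 + 200) // 25] = 5.0
        origins = build_origins([{"midpoint": 5_000, "acs": 5_000, "strand": "-"}])
        out = directional_split(track_from(vals), origins)
        assert out["dominant"].iloc[0] == "upstream"


class TestTopFraction:
    def signals(self, values):
        return pd.DataFrame(
            {"name": [f"o{i}" for i in range(len(values))], "signal": values,
             "valid": True}
        )

    def test_equal_signals_half(self):
        _, k = top_fraction_origins(self.signals([1.0, 1.0, 1.0, 1.0]), 0.5)
        assert k == 2

    def test_skewed_signals_single_origin(self):
        top, k = top_fraction_origins(self.signals([5.0, 3.0, 2.0]), 0.5)
        assert k == 1 and top["signal"].iloc[0] == 5.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=8),
        fraction=st.floats(0.1, 1.0),
    )
    def test_greedy_matches_exhaustive_minimal_subset(self, values, fraction):
        sig = self.signals(values)
        _, k = top_fraction_origins(sig, fraction)
        total = sum(values)
        best = min(
            (
                len(sub)
                for r in range(1, len(values) + 1)
                for sub in itertools.combinations(values, r)
                if sum(sub) >= fraction * total - 1e-9 * total
            ),
        )
        assert k == best

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            top_fraction_origins(self.signals([-1.0, 0.0]), 0.5)


class TestInterOriginDistances:
    def test_two_origins_simple(self):
        sel = build_origins(
            [{"midpoint": 0, "acs": 0}, {"midpoint": 96_000, "acs": 96_000}]
        )
        _, mean = inter_origin_distances(sel)
        assert mean == pytest.approx(96_000)

    def test_three_origins_mean(self):
        sel = build_origins(
            [{"midpoint": 0}, {"midpoint": 10_000}, {"midpoint": 30_000}]
        )
        dists, mean = inter_origin_distances(sel)
        np.testing.assert_array_equal(dists["chr1"], [10_000, 20_000])
        assert mean == pytest.approx(15_000)

    def test_no_cross_chromosome_pairs(self):
        sel = build_origins(
            [
                {"chrom": "chr1", "midpoint": 0},
                {"chrom": "chr1", "midpoint": 40_000},
                {"chrom": "chr2", "midpoint": 1_000_000},
            ]
        )
        dists, mean = inter_origin_distances(sel)
        assert len(dists["chr2"]) == 0
        assert mean == pytest.approx(40_000)
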