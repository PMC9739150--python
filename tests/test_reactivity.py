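from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_histogram2d_mode
from acylsel.reactivity import (
    ReactivityCriteria,
    ReactivitySeries,
    classify_reactive,
    compute_abd,
    compute_d1,
    compute_d2,
    density2d,
    reactive_fraction,
    selectivity_profile,
    summarize,
)


class TestComputeD1:
    def test_tip_at_ceiling_com_is_zero(self, toy):
        # two ceiling carbons around z=5 (COM z=5) and the tip at z=5
        coords = [[0, 0, 4.0], [0, 0, 6.0], [1, 1, 5.0]]
        traj = toy([coords], names=["CB", "CB2", "C16"])
        d1 = compute_d1(traj, [2], [0, 1])
        assert d1[0] == pytest.approx(0.0)

    def test_constructed_offset(self, toy):
        coords = [[0, 0, 8.0], [1, 1, 5.0]]
        traj = toy([coords], names=["CB", "C16"])
        assert compute_d1(traj, [1], [0])[0] == pytest.approx(-3.0)

    def test_mass_weighting_matters(self, toy):
        # O (16) and C (12) at different z: weighted COM is closer to O
        coords = [[0, 0, 0.0], [0, 0, 4.0], [0, 0, 0.0]]
        traj = toy([coords], names=["C1", "OG", "C16"],
                   elements=["C", "O", "C"])
        d1 = compute_d1(traj, [2], [0, 1])
        com_z = (12.011 * 0 + 15.999 * 4) / (12.011 + 15.999)
        assert d1[0] == pytest.approx(-com_z)

    def test_multi_atom_terminal_rejected(self, toy):
        traj = toy(np.zeros((1, 3, 3)))
        with pytest.raises(ValueError, match="exactly 1"):
            compute_d1(traj, [0, 1], [2])


class TestComputeD2AndAbd:
    def test_distance_by_construction(self, toy):
        traj = toy([[[0, 0, 0.0], [3, 4, 0.0]]], names=["SG", "C1"])
        assert compute_d2(traj, [0], [1])[0] == pytest.approx(5.0)

    def test_series_equals_bruteforce(self, small_system):
        traj, _ = small_system
        nu = traj.select("chainID A and resid 156 and name SG")
        cc = traj.select("chainID L and resid 1 and name C1")
        d2 = compute_d2(traj, nu, cc)
        for f in range(0, traj.n_frames, 37):
            expected = np.sqrt(
                ((traj.coordinates[f, nu[0]] - traj.coordinates[f, cc[0]]) ** 2).sum()
            )
            assert d2[f] == pytest.approx(expected, abs=1e-12)

    def test_attack_angle_anti_to_oxygen(self, toy):
        # Nu on the C=O axis beyond C, anti to O -> 180 deg
        coords = [[-2.0, 0, 0], [0.0, 0, 0], [1.23, 0, 0]]
        traj = toy([coords], names=["SG", "C1", "O1"])
        assert compute_abd(traj, [0], [1], [2])[0] == pytest.approx(180.0)

    def test_attack_angle_perpendicular(self, toy):
        coords = [[0.0, 0, 3.0], [0.0, 0, 0], [1.23, 0, 0]]
        traj = toy([coords], names=["SG", "C1", "O1"])
        assert compute_abd(traj, [0], [1], [2])[0] == pytest.approx(90.0)


class TestClassification:
    def test_representative_reactive_frame(self):
        reactive, improper = classify_reactive(np.array([5.1]), np.array([112.0]))
        assert reactive[0] and not improper[0]

    def test_crystal_geometry_is_not_reactive(self):
        # the trapped mutant pose: close-ish but beyond van der Waals contact
        reactive, improper = classify_reactive(np.array([6.6]), np.array([127.0]))
        assert not reactive[0] and not improper[0]

    def test_strict_boundaries(self):
        reactive, improper = classify_reactive(
            np.array([6.0, 5.0]), np.array([120.0, 90.0])
        )
        assert not reactive.any() and not improper.any()

    def test_improper_acute_attack(self):
        reactive, improper = classify_reactive(np.array([5.0]), np.array([40.0]))
        assert improper[0] and not reactive[0]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            classify_reactive(np.zeros(3), np.zeros(2))

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1), st.floats(4.0, 8.0), st.floats(60.0, 120.0))
    def test_tightening_criteria_is_monotone(self, seed, d2_max, abd_min):
        rng = np.random.default_rng(seed)
        d2 = rng.uniform(3, 9, size=200)
        abd = rng.uniform(30, 170, size=200)
        loose, _ = classify_reactive(d2, abd, ReactivityCriteria(d2_max, abd_min))
        tight, _ = classify_reactive(
            d2, abd, ReactivityCriteria(d2_max - 0.5, min(abd_min + 10, 179))
        )
        assert tight.sum() <= loose.sum()
        assert np.all(loose[tight])  # tight reactive frames are a subset


class TestSummarize:
    def test_constant_series(self):
        series = ReactivitySeries.from_measurements(
            d1=np.full(4, -2.0), d2=np.full(4, 5.0), abd=np.full(4, 110.0)
        )
        stats = summarize(series)
        assert stats.d1_mean == pytest.approx(-2.0)
        assert stats.d1_sd == pytest.approx(0.0)
        assert stats.reactive_fraction == 1.0

    def test_hand_example_excludes_far_frame(self):
        series = ReactivitySeries.from_measurements(
            d1=np.zeros(3),
            d2=np.array([5.0, 7.0, 5.0]),
            abd=np.array([100.0, 40.0, 120.0]),
        )
        stats = summarize(series)
        assert stats.d2_mean == pytest.approx(5.0)
        assert stats.abd_mean == pytest.approx(110.0)
        assert stats.n_conditional == 2

    def test_conditional_reactive_switch(self):
        series = ReactivitySeries.from_measurements(
            d1=np.zeros(3),
            d2=np.array([5.0, 5.5, 5.0]),
            abd=np.array([100.0, 40.0, 120.0]),
        )
        stats = summarize(series, conditional="reactive")
        # the abd=40 frame is close but improper, so it drops out
        assert stats.abd_mean == pytest.approx(110.0)
        assert stats.n_conditional == 2

    def test_no_close_frames_flagged_undefined(self):
        series = ReactivitySeries.from_measurements(
            d1=np.zeros(2), d2=np.array([8.0, 9.0]), abd=np.array([100.0, 100.0])
        )
        stats = summarize(series)
        assert not stats.conditional_defined
        assert np.isnan(stats.d2_mean) and np.isnan(stats.abd_mean)

    def test_sample_sd_definition(self):
        series = ReactivitySeries.from_measurements(
            d1=np.array([-1.0, -3.0]), d2=np.full(2, 5.0), abd=np.full(2, 110.0)
        )
        stats = summarize(series)
        assert stats.d1_sd == pytest.approx(np.std([-1, -3], ddof=1))
        assert stats.sd_definition == "sample (n-1)"

    def test_matches_filter_then_average_oracle(self, small_system):
        traj, truth = small_system
        t = truth.table
        series = ReactivitySeries.from_measurements(
            t.d1.values, t.d2.values, t.abd.values
        )
        stats = summarize(series)
        mask = t.d2.values < 6.0
        assert stats.d2_mean == pytest.approx(t.d2.values[mask].mean())
        assert stats.abd_mean == pytest.approx(t.abd.values[mask].mean())
        assert stats.abd_sd == pytest.approx(t.abd.values[mask].std(ddof=1))
        assert stats.reactive_fraction == pytest.approx(t.reactive.mean())


class TestFractionsAndProfile:
    def test_fraction_bookkeeping(self):
        assert reactive_fraction(np.array([True, False, True, False])) == 0.5
        assert reactive_fraction(np.zeros(5, dtype=bool)) == 0.0
        with pytest.raises(ValueError):
            reactive_fraction(np.array([], dtype=bool))

    def test_single_winner_takes_all(self):
        prof = selectivity_profile({"C12": 0.0, "C16": 0.2, "C20": 0.0})
        assert prof.loc["C16", "normalized_reactive_pct"] == pytest.approx(100.0)

    def test_equal_fractions(self):
        prof = selectivity_profile({f"C{k}": 0.3 for k in (12, 14, 16, 18, 20)})
        assert np.allclose(prof["normalized_reactive_pct"], 20.0)

    def test_normalization_arithmetic(self):
        fractions = dict(zip("abcde", [0.05, 0.10, 0.60, 0.30, 0.05]))
        prof = selectivity_profile(fractions)
        expected = 100 * np.array([0.05, 0.10, 0.60, 0.30, 0.05]) / 1.10
        assert np.allclose(prof["normalized_reactive_pct"], expected)
        assert prof["normalized_reactive_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_negative_rejected_and_zero_warns(self):
        with pytest.raises(ValueError):
            selectivity_profile({"C16": -0.1})
        with pytest.warns(UserWarning):
            prof = selectivity_profile({"C12": 0.0, "C16": 0.0})
        assert (prof["normalized_reactive_pct"] == 0).all()

    def test_reactive_plus_improper_bounded(self, benchmark_suite):
        for _, truth in benchmark_suite.values():
            assert truth.realized_reactive_fraction + \
                truth.realized_improper_fraction <= 1.0


class TestDensity2D:
    def test_single_occupied_bin(self):
        dens = density2d(np.full(10, 5.0), np.full(10, 110.0))
        assert dens.counts.sum() == 10
        assert (dens.counts > 0).sum() == 1
        mode = dens.mode
        assert abs(mode[0] - 5.0) <= 0.125 and abs(mode[1] - 110.0) <= 2.5

    def test_mode_in_majority_cluster(self):
        rng = np.random.default_rng(0)
        d2 = np.concatenate([rng.normal(5, 0.05, 900), rng.normal(8, 0.05, 100)])
        abd = np.concatenate([rng.normal(110, 1, 900), rng.normal(60, 1, 100)])
        mode = density2d(d2, abd).mode
        assert abs(mode[0] - 5.0) < 0.5 and abs(mode[1] - 110.0) < 5.0

    def test_tie_break_lowest_d2_then_abd(self):
        d2 = np.array([4.1, 7.1, 4.1, 7.1])
        abd = np.array([100.0, 100.0, 150.0, 150.0])
        mode = density2d(d2, abd).mode
        assert mode[0] < 4.5 and mode[1] < 105.0

    def test_matches_bruteforce_bin_scan(self):
        rng = np.random.default_rng(5)
        d2 = np.concatenate([rng.normal(5, 0.4, 400), rng.normal(7.5, 0.3, 300)])
        abd = np.concatenate([rng.normal(115, 8, 400), rng.normal(55, 6, 300)])
        dens = density2d(d2, abd)
        bx, by, bcounts = brute_histogram2d_mode(d2, abd, dens.d2_edges,
                                                 dens.abd_edges)
        assert np.array_equal(dens.counts, bcounts)
        assert dens.mode == pytest.approx((bx, by))

    def test_empty_series_errors(self):
        with pytest.raises(ValueError):
            density2d(np.array([]), np.array([]))
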