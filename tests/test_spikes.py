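"""Tests for the spike-train analysis primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saccrace import spikes as sp
from _oracles import spearman_oracle, unpaired_permutation_oracle


GRID = np.arange(-300.0, 501.0)


class TestSpikeDensity:
    def test_empty_train_is_zero(self):
        assert np.all(sp.spike_density(np.array([]), GRID) == 0)

    def test_single_spike_peak_height(self):
        sdf = sp.spike_density(np.array([100.0]), GRID)
        peak = 1000.0 / (15.0 * math.sqrt(2 * math.pi))
        i = np.argmax(sdf)
        assert GRID[i] == 100.0
        assert sdf[i] == pytest.approx(peak, rel=1e-6)

    def test_mass_conservation_interior_spikes(self):
        rng = np.random.default_rng(1)
        spikes = rng.uniform(-200, 400, size=37)  # >= 5 sigma from edges
        sdf = sp.spike_density(spikes, GRID)
        integral = np.trapezoid(sdf, GRID) / 1000.0
        assert integral == pytest.approx(37.0, abs=1e-6)

    def test_binned_matrix_agrees_with_exact_kernel(self):
        rng = np.random.default_rng(2)
        # bin-center spike times isolate the kernel-discretization error
        trains = [
            np.sort(rng.integers(-200, 400, 30)).astype(float) for _ in range(4)
        ]
        mat = sp.sdf_matrix(trains, GRID)
        for row, train in zip(mat, trains):
            exact = sp.spike_density(train, GRID)
            assert np.max(np.abs(row - exact)) < 0.3  # spikes/s

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            sp.spike_density(np.array([0.0]), np.arange(0, 100, 5.0))


class TestPopulationAveraging:
    def test_self_normalization_gives_unity(self):
        trace = np.full(100, 40.0)
        mean, se = sp.normalize_and_average([trace], [40.0])
        assert np.allclose(mean, 1.0)
        assert np.all(se == 0)

    def test_two_neuron_average_is_pointwise_mean(self):
        f = np.linspace(0, 1, 50)
        g = np.linspace(1, 0, 50)
        mean, _ = sp.normalize_and_average([f, g], [1.0, 1.0])
        assert np.allclose(mean, (f + g) / 2)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            sp.normalize_and_average([], [])


class TestQuantileBins:
    def test_hundred_trials_first_bin_is_fastest_twenty(self):
        rng = np.random.default_rng(0)
        rts = rng.uniform(100, 400, 100)
        centers, members = sp.quantile_bin_members(rts, 20, 0.20)
        assert len(members) == 20
        assert all(len(m) == 20 for m in members)
        fastest = set(np.argsort(rts)[:20])
        assert set(members[0]) == fastest
        slowest = set(np.argsort(rts)[-20:])
        assert set(members[-1]) == slowest
        assert centers[0] == pytest.approx(0.10)
        assert centers[-1] == pytest.approx(0.90)

    def test_identical_trials_give_identical_traces(self):
        sdfs = np.tile(np.linspace(0, 1, 50), (40, 1))
        rts = np.full(40, 200.0)
        fam = sp.rt_quantile_traces(sdfs, rts, np.arange(50.0), n_bins=20)
        assert np.allclose(fam.traces, fam.traces[0])

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            sp.quantile_bin_members(np.arange(10.0), 20)


class TestActivityMap:
    def test_rows_sorted_by_rt(self):
        rng = np.random.default_rng(3)
        sdfs = rng.random((10, 50))
        rts = rng.uniform(100, 300, 10)
        am = sp.activity_map(sdfs, rts, np.arange(50.0))
        assert np.all(np.diff(am.rts) >= 0)

    def test_identical_trials_smoothing_is_identity(self):
        sdfs = np.tile(np.linspace(0, 5, 30), (5, 1))
        am = sp.activity_map(sdfs, np.full(5, 150.0), np.arange(30.0))
        assert np.allclose(am.smoothed, am.rates)

    def test_needs_three_trials(self):
        with pytest.raises(ValueError):
            sp.activity_map(np.zeros((2, 10)), np.array([1.0, 2.0]), np.arange(10.0))


class TestPeakTiming:
    def _sdfs_with_peaks(self, peaks, grid):
        out = np.zeros((len(peaks), len(grid)))
        for i, pk in enumerate(peaks):
            out[i] = np.exp(-0.5 * ((grid - pk) / 20.0) ** 2)
        return out

    @pytest.mark.parametrize(
        "b0,b1",
        [(80.0, 0.0), (-30.0, 1.0), (50.0, 0.5)],
    )
    def test_noiseless_fit_recovers_coefficients(self, b0, b1):
        grid = np.arange(-100.0, 600.0)
        rts = np.linspace(150, 400, 12)
        peaks = b0 + b1 * rts
        sdfs = self._sdfs_with_peaks(peaks, grid)
        fit0, fit1 = sp.fit_peak_timing(sdfs, rts, grid)
        assert fit0 == pytest.approx(b0, abs=1.5)
        assert fit1 == pytest.approx(b1, abs=0.01)

    def test_degenerate_rt_variance_rejected(self):
        grid = np.arange(-50.0, 200.0)
        sdfs = self._sdfs_with_peaks([80] * 6, grid)
        with pytest.raises(ValueError):
            sp.fit_peak_timing(sdfs, np.full(6, 200.0), grid)


class TestPeakResponse:
    def test_visual_cell_peak_time_is_rt_independent(self):
        _, tp = sp.peak_response(np.array([]), 300.0, 80.0, 0.0)
        assert tp == 80.0

    def test_movement_cell_peak_time_tracks_saccade(self):
        _, tp = sp.peak_response(np.array([]), 250.0, -30.0, 1.0)
        assert tp == 220.0

    def test_rate_is_count_over_window(self):
        spikes = np.linspace(60.0, 99.0, 10)
        rp, tp = sp.peak_response(spikes, 100.0, 80.0, 0.0, window_ms=100.0)
        assert tp == 80.0
        assert rp == pytest.approx(100.0)

    def test_truncated_window_uses_covered_duration(self):
        spikes = np.array([10.0, 20.0, 30.0])
        with pytest.warns(UserWarning):
            rp, _ = sp.peak_response(
                spikes, 100.0, 0.0, 0.0, window_ms=100.0, trial_window=(0.0, 400.0)
            )
        assert rp == pytest.approx(1000.0 * 3 / 50.0)


class TestResponseOnset:
    def test_step_response_onset_near_step_time(self):
        rng = np.random.default_rng(42)
        # silent baseline, strong sustained step at 120 ms
        spikes = np.sort(rng.uniform(120, 400, 60))
        ton, ron = sp.response_onset(spikes, tp_ms=300.0)
        assert 110.0 <= ton <= 135.0
        assert ron > 0

    def test_flat_trial_has_no_onset(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(-250, 400, 10))
        ton, ron = sp.response_onset(spikes, tp_ms=300.0)
        assert math.isnan(ton)

    def test_zero_spikes_near_onset_gives_zero_rate(self):
        # single distant burst triggers onset; count the window honestly
        ton, ron = sp.response_onset(np.array([]), tp_ms=300.0)
        assert math.isnan(ton) and math.isnan(ron)


class TestBuildupRate:
    def test_flat_excursion_is_zero(self):
        assert sp.buildup_rate(60.0, 60.0, 180.0, 80.0) == 0.0

    def test_worked_arithmetic(self):
        assert sp.buildup_rate(60.0, 10.0, 180.0, 80.0) == pytest.approx(0.5)

    def test_undefined_when_no_rise_interval(self):
        assert math.isnan(sp.buildup_rate(60.0, 10.0, 100.0, 100.0))
        assert math.isnan(sp.buildup_rate(60.0, 10.0, 100.0, math.nan))


class TestWindowRates:
    def test_baseline_rate_arithmetic(self):
        spikes = np.array([-240.0, -200.0, -150.0, -100.0, -20.0])
        rb, rm, rsac = sp.window_rates(spikes, 300.0)
        assert rb == pytest.approx(20.0)
        assert rm == 0.0

    def test_silent_trial_all_zero(self):
        assert sp.window_rates(np.array([]), 250.0) == (0.0, 0.0, 0.0)

    def test_homogeneous_rate_recovered_in_all_windows(self):
        rng = np.random.default_rng(5)
        rate = 40.0  # spikes/s
        n_rep = 400
        rb_all, rm_all, rs_all = [], [], []
        for _ in range(n_rep):
            n = rng.poisson(rate * 0.65)  # 650 ms of recording
            spikes = np.sort(rng.uniform(-250, 400, n))
            rb, rm, rs = sp.window_rates(spikes, 400.0)
            rb_all.append(rb)
            rm_all.append(rm)
            rs_all.append(rs)
        for vals, w in ((rb_all, 0.25), (rm_all, 0.4), (rs_all, 0.02)):
            se = math.sqrt(rate / (w * n_rep))
            assert np.mean(vals) == pytest.approx(rate, abs=3.5 * se)


class TestSpearman:
    def test_perfect_monotone_relations(self):
        x = np.arange(10.0)
        rho, _ = sp.spearman_correlations(x, x**3 + 2)
        assert rho == pytest.approx(1.0)
        rho, _ = sp.spearman_correlations(x, -np.sqrt(x + 1))
        assert rho == pytest.approx(-1.0)

    def test_eight_pair_example_matches_rank_oracle(self):
        x = [3.1, 0.2, 5.5, 5.5, 2.0, 7.7, 1.1, 4.2]
        y = [210.0, 300.0, 180.0, 240.0, 260.0, 150.0, 290.0, 190.0]
        rho, _ = sp.spearman_correlations(np.array(x), np.array(y))
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_constant_metric_undefined(self):
        rho, p = sp.spearman_correlations(np.full(8, 2.0), np.arange(8.0))
        assert math.isnan(rho) and math.isnan(p)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=6, max_size=12, unique=True))
    def test_invariance_under_monotone_transform(self, vals):
        xs = np.array(vals, dtype=float) / 20.0
        rng = np.random.default_rng(len(vals))
        ys = rng.normal(size=len(xs))
        r1, _ = sp.spearman_correlations(xs, ys)
        r2, _ = sp.spearman_correlations(np.exp(xs / 25.0), ys)
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestPermutationTest:
    def test_identical_paired_groups_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = sp.permutation_test(a, a.copy(), paired=True)
        assert res.p == 1.0

    def test_exhaustive_matches_enumeration_oracle(self):
        a = [3.2, 4.1, 5.6, 2.8]
        b = [7.9, 8.3, 6.5, 9.1]
        res = sp.permutation_test(np.array(a), np.array(b))
        assert res.p == pytest.approx(unpaired_permutation_oracle(a, b), abs=1e-12)

    def test_wide_separation_hits_floor(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(50, 1, 20)
        res = sp.permutation_test(a, b, n_perm=20_000, rng=rng)
        assert res.p == pytest.approx(1 / 20_000)
        assert res.at_floor
        assert str(res) == "p<5e-05"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            sp.permutation_test(np.array([1.0]), np.array([1.0, 2.0]))


class TestRtMatch:
    def test_worked_example_two_pairs(self):
        a = np.array([150.0, 200.0, 300.0])
        b = np.array([160.0, 210.0, 400.0])
        for seed in range(6):
            ia, ib = sp.rt_match(a, b, 15.0, np.random.default_rng(seed))
            assert len(ia) == 2
            pairs = {(a[i], b[j]) for i, j in zip(ia, ib)}
            assert pairs == {(150.0, 160.0), (200.0, 210.0)}

    def test_identical_multisets_fully_match(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(100, 400, 30)
        ia, ib = sp.rt_match(a, a.copy(), 15.0, rng)
        assert len(ia) == 30

    def test_disjoint_sets_give_empty_match(self):
        ia, ib = sp.rt_match(
            np.array([100.0, 120.0]), np.array([200.0, 260.0]), 15.0,
            np.random.default_rng(0),
        )
        assert len(ia) == 0

    def test_accepted_pairs_within_tolerance_and_means_close(self):
        rng = np.random.default_rng(9)
        a = rng.normal(200, 40, 80)
        b = rng.normal(260, 60, 80)
        ia, ib = sp.rt_match(a, b, 15.0, rng)
        assert len(ia) == len(ib)
        assert np.all(np.abs(a[ia] - b[ib]) < 15.0)
        if len(ia):
            assert abs(a[ia].mean() - b[ib].mean()) < 15.0


class TestClassification:
    @pytest.mark.parametrize(
        "beta1,expected",
        [(0.05, "excluded"), (0.30, "V"), (0.60, "VM"), (0.95, "M")],
    )
    def test_categories(self, beta1, expected):
        assert sp.classify_neuron(beta1) == expected

    def test_nonfinite_index_rejected(self):
        with pytest.raises(ValueError):
            sp.classify_neuron(math.inf)


class TestTrialSelection:
    def _trials(self, blocks):
        import pandas as pd

        rows = []
        for b, (cond, n) in enumerate(blocks):
            for j in range(n):
                rows.append((b, j, cond))
        return pd.DataFrame(rows, columns=["block", "trial_in_block", "condition"])

    def test_block_of_ten_keeps_two(self):
        out = sp.discard_block_start(self._trials([("congruent", 10)]), k=8)
        assert len(out) == 2

    def test_k_zero_is_identity(self):
        t = self._trials([("congruent", 10), ("incongruent", 5)])
        assert len(sp.discard_block_start(t, k=0)) == len(t)

    def test_short_blocks_all_dropped_but_adr_kept(self):
        out = sp.discard_block_start(
            self._trials([("congruent", 5), ("adr", 5)]), k=8
        )
        assert set(out["condition"]) == {"adr"}
        assert len(out) == 5
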