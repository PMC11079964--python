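"""CPP quantities: cluster averaging, grand ERPs, decision-time binning,
slope estimation, the slope-vs-bin profile, window sweep, topography."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wmcpp import cpp
from wmcpp.cpp import (
    BinnedErp,
    bin_by_decision_time,
    cluster_average,
    erp_image,
    grand_erp,
    slope,
    slope_bin_profile,
    topography_values,
    window_sweep,
)
from wmcpp.errors import ConfigError, DataError
from wmcpp.preprocess import epoch
from wmcpp.synth import expected_slope

from conftest import noiseless_config, toy_epochs
from wmcpp.synth import simulate_participant


def _binned(bin_means, times_ms, dt_ms, alignment="response"):
    bin_means = np.asarray(bin_means, dtype=float)
    return BinnedErp(
        participant_id="toy",
        bin_means=bin_means,
        bin_mean_dt_ms=np.asarray(dt_ms, dtype=float),
        bin_counts=np.ones(bin_means.shape[0], dtype=int),
        alignment=alignment,
        times_ms=np.asarray(times_ms, dtype=float),
    )


class TestClusterAverage:
    def test_identical_channels_passthrough(self):
        times = np.arange(0, 41, 4.0)
        x = np.random.default_rng(0).normal(size=(4, 1, times.size))
        data = np.repeat(x, 2, axis=1)
        ep = toy_epochs(data, times)
        out = cluster_average(ep, ["ch0", "ch1"])
        np.testing.assert_allclose(out, x[:, 0, :])

    def test_mean_of_two_channels(self):
        times = np.arange(0, 9, 4.0)
        data = np.stack([np.full((1, 3), 1.0), np.full((1, 3), 3.0)], axis=1)
        ep = toy_epochs(data, times)
        np.testing.assert_allclose(cluster_average(ep, ["ch0", "ch1"]), 2.0)

    def test_default_cluster_has_five_channels(self):
        assert cpp.CLUSTER_CHANNELS == ["Pz", "CPz", "POz", "P1", "P2"]

    def test_missing_channel_named(self):
        times = np.arange(0, 9, 4.0)
        ep = toy_epochs(np.zeros((1, 1, times.size)), times)
        with pytest.raises(ConfigError, match="Pz"):
            cluster_average(ep, ["Pz"])


class TestGrandErp:
    def test_identical_participants_zero_sem(self):
        m = np.tile(np.linspace(0, 1, 10), (4, 1))
        mean, sem = grand_erp(m)
        np.testing.assert_allclose(sem, 0.0)

    def test_two_participant_hand_computation(self):
        mean, sem = grand_erp(np.array([[1.0], [3.0]]))
        assert mean[0] == pytest.approx(2.0)
        assert sem[0] == pytest.approx(1.0)  # sd sqrt(2) / sqrt(2)

    def test_single_participant_sem_missing(self):
        mean, sem = grand_erp(np.ones((1, 5)))
        assert np.isnan(sem).all()


class TestBinning:
    def test_eight_trials_four_even_bins(self):
        rng = np.random.default_rng(0)
        series = rng.normal(size=(8, 5))
        dt = np.array([900, 100, 500, 700, 300, 800, 200, 600], dtype=float)
        b = bin_by_decision_time(series, dt, 4, np.arange(5.0), "response")
        np.testing.assert_array_equal(b.bin_counts, [2, 2, 2, 2])
        np.testing.assert_allclose(b.bin_mean_dt_ms, [150, 400, 650, 850])

    def test_ten_trials_remainders_to_earliest_bins(self):
        series = np.zeros((10, 3))
        dt = np.arange(10, dtype=float) * 100
        b = bin_by_decision_time(series, dt, 4, np.arange(3.0), "response")
        np.testing.assert_array_equal(b.bin_counts, [3, 3, 2, 2])

    @pytest.mark.parametrize("n_bins", [4, 100])
    def test_supported_bin_counts(self, n_bins):
        rng = np.random.default_rng(1)
        series = rng.normal(size=(200, 4))
        dt = rng.uniform(200, 2000, size=200)
        b = bin_by_decision_time(series, dt, n_bins, np.arange(4.0), "response")
        assert b.n_bins == n_bins
        assert np.all(np.diff(b.bin_mean_dt_ms) >= 0)

    def test_more_bins_than_trials_rejected(self):
        with pytest.raises(DataError):
            bin_by_decision_time(
                np.zeros((3, 2)), np.arange(3.0), 4, np.arange(2.0), "response"
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(4, 60),
        k=st.integers(1, 8),
        seed=st.integers(0, 1000),
    )
    def test_binning_is_a_partition(self, n, k, seed):
        """Bins are disjoint, cover all trials, and sizes differ by <= 1."""
        k = min(k, n)
        rng = np.random.default_rng(seed)
        dt = rng.uniform(200, 2000, size=n)
        series = rng.normal(size=(n, 3))
        b = bin_by_decision_time(series, dt, k, np.arange(3.0), "response")
        assert b.bin_counts.sum() == n
        assert b.bin_counts.max() - b.bin_counts.min() <= 1
        assert np.all(np.diff(b.bin_mean_dt_ms) >= 0)


class TestErpImage:
    def test_single_participant_passthrough(self):
        b = _binned(np.random.default_rng(0).normal(size=(4, 6)),
                    np.arange(6.0), [300, 500, 700, 900])
        image, dt = erp_image([b])
        np.testing.assert_array_equal(image, b.bin_means)
        np.testing.assert_array_equal(dt, b.bin_mean_dt_ms)

    def test_two_constant_participants_average(self):
        times = np.arange(6.0)
        b0 = _binned(np.zeros((3, 6)), times, [1, 2, 3])
        b2 = _binned(np.full((3, 6), 2.0), times, [3, 4, 5])
        image, dt = erp_image([b0, b2])
        np.testing.assert_allclose(image, 1.0)
        np.testing.assert_allclose(dt, [2, 3, 4])

    def test_axis_mismatch_rejected(self):
        b0 = _binned(np.zeros((3, 6)), np.arange(6.0), [1, 2, 3])
        b1 = _binned(np.zeros((4, 6)), np.arange(6.0), [1, 2, 3, 4])
        with pytest.raises(DataError):
            erp_image([b0, b1])


class TestSlope:
    def test_exact_line(self):
        """A line gaining 2 uV per 100 ms has slope 20 uV/s."""
        times = np.arange(-500, 1, 4.0)
        series = 2.0 * times / 100.0
        assert slope(series, times, (-500, 0)) == pytest.approx(20.0, rel=1e-12)

    def test_constant_series_zero(self):
        times = np.arange(-500, 1, 4.0)
        assert slope(np.full(times.size, 3.0), times, (-500, 0)) == pytest.approx(0.0)

    def test_five_point_toy(self):
        """(0,1,2,3,4) uV at 4 ms spacing -> 250 uV/s."""
        times = np.arange(5) * 4.0
        assert slope(np.arange(5.0), times, (0, 16)) == pytest.approx(250.0)

    def test_too_few_samples_is_missing(self):
        times = np.arange(5) * 4.0
        assert np.isnan(slope(np.arange(5.0), times, (0.0, 4.0)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(offset=st.floats(-100.0, 100.0), seed=st.integers(0, 100))
    def test_baseline_shift_invariance(self, offset, seed):
        """Slope is unchanged by any constant baseline shift."""
        times = np.arange(-500, 1, 4.0)
        y = np.random.default_rng(seed).normal(size=times.size)
        a = slope(y, times, (-500, -50))
        b = slope(y + offset, times, (-500, -50))
        assert a == pytest.approx(b, abs=1e-9)

    def test_matches_generator_ground_truth_inside_ramp(self):
        """On noiseless slow trials whose window lies inside the ramp, the
        estimated slope matches A/(DT - t0) within 5%."""
        cfg = noiseless_config(
            n_trials=4, dt_shift_ms=900.0, dt_lognorm_mu=5.6, dt_lognorm_sigma=0.1
        )
        ses = simulate_participant(cfg, "p", 12)
        ep = epoch(ses, "response", (-700.0, 100.0))
        iPz = ep.channel_index("Pz")
        from wmcpp.montage import spatial_weights

        w = spatial_weights(ep.channel_positions, cfg.topo_center, cfg.topo_width)
        for i in range(ep.n_trials):
            dt = ep.metadata.loc[i, "decision_time_ms"]
            est = slope(ep.data[i, iPz], ep.times_ms, (-500.0, -50.0))
            truth = w[iPz] * expected_slope(cfg, "selection", dt)
            assert est == pytest.approx(truth, rel=0.05)


class TestSlopeBinProfile:
    def test_perfectly_decreasing_slopes_give_r_minus_one(self):
        times = np.arange(-500, 1, 4.0)
        means = np.vstack([(4 - b) * times / 1000.0 for b in range(4)])
        b = _binned(means, times, [300, 500, 700, 900])
        res = slope_bin_profile(b, (-500, -50))
        assert np.all(np.diff(res.slopes_per_bin) < 0)
        assert res.r_slope_vs_bin == pytest.approx(-1.0)

    def test_equal_slopes_flagged_as_undefined(self):
        times = np.arange(-500, 1, 4.0)
        means = np.tile(times / 1000.0, (4, 1))
        b = _binned(means, times, [300, 500, 700, 900])
        with pytest.warns(UserWarning):
            res = slope_bin_profile(b, (-500, -50))
        assert np.isnan(res.r_slope_vs_bin)

    def test_cue_aligned_binning_rejected(self):
        times = np.arange(-500, 1, 4.0)
        b = _binned(np.zeros((4, times.size)), times, [1, 2, 3, 4], alignment="cue")
        with pytest.raises(ConfigError):
            slope_bin_profile(b, (-500, -50))

    def test_noiseless_participant_recovers_negative_gradient(self):
        """Bound-fixed generator: quartile slopes fall with bin decision time."""
        from wmcpp.pipeline import analyze_participant
        from wmcpp.preprocess import PreprocessConfig
        from wmcpp.cpp import AnalysisConfig

        cfg = noiseless_config(n_trials=32)
        ses = simulate_participant(cfg, "p", 21)
        first = analyze_participant(ses, PreprocessConfig(), AnalysisConfig())
        res = first["slope_result"]
        bq = first["binned_quartile_resp"]
        assert np.all(np.diff(bq.bin_mean_dt_ms) > 0)
        assert np.all(np.diff(res.slopes_per_bin) < 0)
        assert res.r_slope_vs_bin < -0.8


class TestWindowSweep:
    def test_apriori_cell_present_and_valid_grid(self):
        rng = np.random.default_rng(4)
        times = np.arange(-1200, 1, 4.0)
        binned = [
            _binned(rng.normal(size=(4, times.size)), times, [300, 500, 700, 900])
            for _ in range(6)
        ]
        sw = window_sweep(binned)
        i = np.where(sw.starts_ms == -500)[0][0]
        j = np.where(sw.ends_ms == -50)[0][0]
        assert np.isfinite(sw.t_map[i, j])
        assert sw.apriori_window_ms == (-500.0, -50.0)
        # min-window rule: (-250, -200) is a 50 ms window -> invalid
        i2 = np.where(sw.starts_ms == -250)[0][0]
        j2 = np.where(sw.ends_ms == -200)[0][0]
        assert np.isnan(sw.t_map[i2, j2])

    def test_null_binned_data_false_positive_rate(self):
        """On pure-noise bins the a priori cell's |t| exceeds the 5% critical
        value at roughly the nominal rate."""
        rng = np.random.default_rng(99)
        times = np.arange(-600, 1, 4.0)
        crit = 2.0639  # two-sided t, df = 24, alpha = .05
        hits = 0
        reps = 200
        for _ in range(reps):
            binned = [
                _binned(rng.normal(size=(4, times.size)), times, [300, 500, 700, 900])
                for _ in range(25)
            ]
            sw = window_sweep(
                binned, starts_ms=[-500.0], ends_ms=[-50.0], min_window_ms=100.0
            )
            if abs(sw.t_map[0, 0]) > crit:
                hits += 1
        assert 0.015 <= hits / reps <= 0.105


class TestTopography:
    def test_constant_field(self):
        times = np.arange(-100, 101, 4.0)
        ep = toy_epochs(np.full((3, 4, times.size), 5.0), times)
        labels, vals = topography_values([ep], (-100, 0))
        np.testing.assert_allclose(vals, 5.0)

    def test_window_outside_epoch_rejected(self):
        times = np.arange(-100, 101, 4.0)
        ep = toy_epochs(np.zeros((1, 2, times.size)), times)
        with pytest.raises(ConfigError):
            topography_values([ep], (500, 600))

    def test_synthetic_cpp_peaks_near_topo_center(self, noiseless_session):
        ep = epoch(noiseless_session, "response", (-300.0, 0.0))
        labels, vals = topography_values([ep], (-300.0, 0.0))
        peak = labels[int(np.argmax(vals))]
        assert peak in {"Pz", "CPz", "POz", "P1", "P2", "CP1", "CP2"}

    def test_condition_contrast_window_supported(self, noiseless_session):
        ep = epoch(noiseless_session, "response", (-1500.0, 500.0))
        labels, vals = topography_values([ep], (-600.0, -300.0))
        assert np.isfinite(vals).all()
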