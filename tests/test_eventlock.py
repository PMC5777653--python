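"""ROI localization, region curves, event-locked percent change."""

import numpy as np
import pytest

from dfcd import eventlock, fcd, synth
from dfcd.datatypes import EventTrain, RegionSet
from tests.conftest import make_bold


class TestGlmLocalizer:
    def test_noiseless_voxel_capped_and_selected(self, hrf, single_event):
        spec = synth.NetworkSpec(
            cluster_assignments=np.array([1, 0, 0, 0, 0]),
            coupling_amplitude={0: 0.0, 1: 1.0}, noise_sd=0.0, baseline=0.0)
        sim = synth.generate_bold(spec, single_event, hrf, 0.66, 120, seed=0)
        # add noise to background voxels only, keeping voxel 0 a perfect fit
        rng = np.random.default_rng(1)
        sim.bold.data[1:] += rng.normal(size=sim.bold.data[1:].shape)
        roi, t_map = eventlock.glm_localizer(sim.bold, single_event, hrf,
                                             threshold_quantile=0.8)
        assert 0 in roi
        assert t_map[0] == pytest.approx(1e6)  # capped, not inf

    def test_type_one_rate_on_pure_noise(self, hrf, rng):
        # t for a null voxel is ~ Student; exceedance of the 0.999 quantile
        # is ~ 0.001 over many voxels
        n_vox, t_len, tr = 4000, 300, 0.66
        events = synth.make_event_train(8, 15, 25, 0.5, 160, seed=3)
        bold = make_bold(rng.standard_normal((n_vox, t_len)), tr)
        _, t_map = eventlock.glm_localizer(bold, events, hrf,
                                           threshold_quantile=0.99)
        from scipy import stats as sstats
        t_crit = sstats.t.ppf(0.999, t_len - 2)
        rate = np.mean(t_map > t_crit)
        se = np.sqrt(0.001 * 0.999 / n_vox)
        assert abs(rate - 0.001) < 4 * se

    def test_recovers_ground_truth_cluster(self, hrf):
        # localizer-style world: strong response (gain >> noise), as in a
        # blocked localizer run
        net = synth.demo_network(shape=(12, 12, 4), visual_gain=25.0)
        events = synth.make_event_train(12, 15, 25, 0.5, 280, seed=5)
        sim = synth.generate_bold(net, events, hrf, 0.66, 320, seed=6)
        cluster = np.flatnonzero(net.cluster_assignments == 1)
        roi, _ = eventlock.glm_localizer(
            sim.bold, events, hrf,
            threshold_quantile=1.0 - cluster.size / net.n_voxels)
        recovered = np.isin(cluster, roi).mean()
        false_rate = (~np.isin(roi, np.flatnonzero(
            net.cluster_assignments > 0))).mean()
        assert recovered >= 0.95
        assert false_rate <= 0.05

    def test_constant_regressor_rejected(self, hrf, rng):
        bold = make_bold(rng.standard_normal((3, 50)), 1.0)
        empty = EventTrain(onsets=np.array([]), durations=np.array([]))
        with pytest.raises(ValueError):
            eventlock.glm_localizer(bold, empty, hrf)


class TestRegionTimecourse:
    def test_single_voxel_region_returns_its_series(self, rng):
        bold = make_bold(rng.standard_normal((5, 30)), 1.0)
        times, curve = eventlock.extract_region_timecourse(bold, np.array([2]))
        np.testing.assert_array_equal(curve, bold.data[2])
        np.testing.assert_allclose(times, np.arange(30.0))

    def test_two_voxel_mean(self, rng):
        bold = make_bold(rng.standard_normal((5, 30)), 1.0)
        _, curve = eventlock.extract_region_timecourse(bold, np.array([1, 3]))
        np.testing.assert_allclose(curve, (bold.data[1] + bold.data[3]) / 2)

    def test_region_set_mean_matches_loop_oracle(self, rng):
        bold = make_bold(rng.standard_normal((10, 40)), 1.0)
        labels = np.array([1, 1, 2, 2, 2, 0, 0, 1, 2, 0])
        regions = RegionSet(labels=labels, names={1: "a", 2: "b"})
        _, curve = eventlock.extract_region_timecourse(bold, regions, 2)
        rows = [i for i in range(10) if labels[i] == 2]
        expected = sum(bold.data[i] for i in rows) / len(rows)
        np.testing.assert_allclose(curve, expected)

    def test_fcd_series_region_mean(self, rng):
        bold = make_bold(rng.standard_normal((10, 60)), 0.5)
        series = fcd.sliding_fcd(bold, None, fcd.WindowSpec(5.0, 10), p=0.2)
        _, curve = eventlock.extract_region_timecourse(series, np.array([0, 4]))
        np.testing.assert_allclose(
            curve, series.degrees[[0, 4]].mean(axis=0))

    def test_empty_region_rejected(self, rng):
        bold = make_bold(rng.standard_normal((5, 30)), 1.0)
        with pytest.raises(ValueError):
            eventlock.extract_region_timecourse(bold, np.array([], dtype=int))


class TestEpochPercentChange:
    def grid(self, t_end=300.0, dt=0.66):
        return np.arange(0.0, t_end, dt)

    def test_constant_curve_gives_zero_percent(self):
        times = self.grid()
        events = EventTrain(onsets=np.array([60.0, 120.0]),
                            durations=np.array([0.5, 0.5]))
        ep = eventlock.epoch_percent_change(times, np.full(times.size, 7.0),
                                            events)
        np.testing.assert_allclose(ep.values, 0.0, atol=1e-12)

    def test_thirty_percent_step(self):
        # B = 10, value 13 after onset -> +30%
        times = self.grid(dt=1.0)
        values = np.where(times < 100.0, 10.0, 13.0)
        events = EventTrain(onsets=np.array([100.0]), durations=np.array([0.5]))
        ep = eventlock.epoch_percent_change(times, values, events)
        post = ep.values[0][ep.offsets >= 0]
        np.testing.assert_allclose(post, 30.0)
        np.testing.assert_allclose(ep.values[0][ep.offsets < -0.5], 0.0)

    def test_baseline_window_is_half_open(self):
        # a spike exactly at onset must not leak into the baseline
        times = np.arange(0.0, 200.0, 1.0)
        values = np.full(times.size, 5.0)
        values[100] = 50.0
        events = EventTrain(onsets=np.array([100.0]), durations=np.array([0.5]))
        ep = eventlock.epoch_percent_change(times, values, events)
        at_zero = ep.values[0][np.isclose(ep.offsets, 0.0)]
        assert at_zero[0] == pytest.approx(100 * 45 / 5)

    def test_nonpositive_baseline_flagged(self):
        times = self.grid(dt=1.0)
        values = np.zeros(times.size)
        events = EventTrain(onsets=np.array([100.0]), durations=np.array([0.5]))
        ep = eventlock.epoch_percent_change(times, values, events)
        assert not ep.valid[0]
        with pytest.raises(ValueError):
            _ = ep.average

    def test_subtract_mode_has_no_baseline_bias(self, rng):
        # stationary noisy curve: event-averaged subtracted change ~ 0
        times = np.arange(0.0, 4000.0, 1.0)
        values = 10 + rng.standard_normal(times.size)
        onsets = np.arange(50.0, 3950.0, 40.0)
        events = EventTrain(onsets=onsets, durations=np.full(onsets.size, 0.5))
        ep = eventlock.epoch_percent_change(times, values, events,
                                            mode="subtract")
        assert np.abs(ep.average).max() < 5 * 1.1 / np.sqrt(len(events))

    def test_pooled_percent_mode_unbiased_on_stationary_series(self, rng):
        # the default percent mode must not inflate far offsets either
        times = np.arange(0.0, 4000.0, 1.0)
        values = 10 + rng.standard_normal(times.size)
        onsets = np.arange(50.0, 3950.0, 40.0)
        events = EventTrain(onsets=onsets, durations=np.full(onsets.size, 0.5))
        ep = eventlock.epoch_percent_change(times, values, events)
        far = ep.average[np.abs(ep.offsets) > 10]
        assert np.abs(far).mean() < 3.0  # percent of a baseline of 10

    def test_edge_events_dropped_without_changing_others(self):
        times = self.grid(dt=1.0)
        values = np.sin(times / 20.0) + 2.0
        full = EventTrain(onsets=np.array([100.0, 150.0]),
                          durations=np.array([0.5, 0.5]))
        with_edge = EventTrain(onsets=np.array([5.0, 100.0, 150.0, 295.0]),
                               durations=np.full(4, 0.5))
        a = eventlock.epoch_percent_change(times, values, full)
        b = eventlock.epoch_percent_change(times, values, with_edge)
        assert b.n_dropped == 2
        np.testing.assert_allclose(a.values, b.values)

    def test_scale_invariance_after_normalization(self, rng, hrf):
        # multiplying the raw degree field by a constant cancels in the
        # normalized percent-change curves
        bold = make_bold(rng.standard_normal((20, 300)), 0.66)
        events = EventTrain(onsets=np.array([60.0, 120.0]),
                            durations=np.array([0.5, 0.5]))
        raw = fcd.sliding_fcd(bold, None, fcd.WindowSpec(13.2, 20), p=0.2)
        norm1 = fcd.normalize_fcd(raw)
        scaled = fcd.FcdSeries(
            degrees=raw.degrees * 7.0, window=raw.window,
            r_threshold=raw.r_threshold, time_centers=raw.time_centers,
            tr=raw.tr, voxel_rows=raw.voxel_rows, mask_index=raw.mask_index,
            space_shape=raw.space_shape)
        norm2 = fcd.normalize_fcd(scaled)
        rows = np.array([0, 5])
        t1, c1 = eventlock.extract_region_timecourse(norm1, rows)
        _, c2 = eventlock.extract_region_timecourse(norm2, rows)
        e1 = eventlock.epoch_percent_change(t1, c1, events)
        e2 = eventlock.epoch_percent_change(t1, c2, events)
        np.testing.assert_allclose(e1.values, e2.values, atol=1e-9)


class TestEpochGlobalMeanChange:
    def test_region_at_global_mean_gives_zero(self):
        times = np.arange(0.0, 400.0, 0.66)
        events = EventTrain(onsets=np.array([100.0, 200.0]),
                            durations=np.array([1.0, 1.0]))
        ep = eventlock.epoch_global_mean_change(times, np.ones(times.size),
                                                events)
        np.testing.assert_allclose(ep.values, 0.0, atol=1e-12)
        assert ep.offsets[0] <= -20.0 + 0.66 and ep.offsets[-1] >= 30.0 - 0.66

    def test_150_percent_arithmetic(self):
        times = np.arange(0.0, 400.0, 1.0)
        values = np.ones(times.size)
        values[150] = 2.5
        events = EventTrain(onsets=np.array([150.0]), durations=np.array([1.0]))
        ep = eventlock.epoch_global_mean_change(times, values, events)
        assert ep.values[0][np.isclose(ep.offsets, 0.0)][0] == pytest.approx(150.0)

    def test_ied_burst_locked_maximum(self, hrf):
        # IED emulation: 30 min at TR 0.66 with sparse strong coupling events;
        # event-locked maximum within window/2 + TR of the transient peak
        net = synth.demo_network(shape=(8, 8, 2), coupling_modulation=3.0)
        ied = synth.make_event_train(8, 80, 200, 2.0, 1700, seed=2,
                                     label="ied")
        sim = synth.generate_bold(net, ied, hrf, 0.66, 1800, seed=3)
        wspec = fcd.WindowSpec.from_seconds(13.2, 0.66)
        norm = fcd.normalize_fcd(fcd.sliding_fcd(sim.bold, None, wspec))
        rows = np.flatnonzero(net.cluster_assignments == 1)
        times, curve = eventlock.extract_region_timecourse(norm, rows)
        ep = eventlock.epoch_global_mean_change(times, curve, ied)
        t_max = ep.offsets[np.argmax(ep.average)]
        assert abs(t_max - hrf.peak_delay) <= 13.2 / 2 + 0.66 + net.coupling_width


class TestHemodynamicResponse:
    def test_noiseless_recovery_up_to_scale(self, hrf, single_event):
        spec = synth.NetworkSpec(
            cluster_assignments=np.array([1, 1]),
            coupling_amplitude={1: 2.0}, noise_sd=0.0, baseline=100.0)
        sim = synth.generate_bold(spec, single_event, hrf, 0.66, 120, seed=0)
        offsets, curve = eventlock.extract_hemodynamic_response(
            sim.bold, np.array([0, 1]), single_event)
        truth = synth.event_regressor(single_event, hrf, 0.66,
                                      sim.bold.n_timepoints)
        j0 = int(np.argmin(np.abs(sim.bold.times - single_event.onsets[0])))
        truth_seg = truth[j0: j0 + offsets.size]
        scale = curve.max() / truth_seg.max()
        rms = np.sqrt(np.mean((curve - scale * truth_seg) ** 2))
        assert rms < 1e-6

    def test_peak_latency_matches_hrf(self, hrf, single_event):
        net = synth.demo_network(shape=(8, 8, 2))
        events = synth.make_event_train(10, 20, 30, 0.5, 280, seed=4)
        sim = synth.generate_bold(net, events, hrf, 0.66, 320, seed=4)
        rows = np.flatnonzero(net.cluster_assignments == 1)
        offsets, curve = eventlock.extract_hemodynamic_response(
            sim.bold, rows, events)
        lat = offsets[np.argmax(curve)]
        assert abs(lat - (hrf.peak_delay + 0.25)) <= 1.5  # +0.25: boxcar center

    def test_zero_gain_cluster_flat(self, hrf, single_event, rng):
        spec = synth.NetworkSpec(
            cluster_assignments=np.array([0] * 30),
            coupling_amplitude={0: 0.0}, noise_sd=1.0, baseline=100.0)
        sim = synth.generate_bold(spec, single_event, hrf, 0.66, 120, seed=1)
        offsets, curve = eventlock.extract_hemodynamic_response(
            sim.bold, np.arange(30), single_event)
        # 30 voxels of sd-1 noise on baseline 100: percent change ~ N(0, 0.18)
        assert np.abs(curve).max() < 1.5
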