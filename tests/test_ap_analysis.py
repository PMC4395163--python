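import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from camapper import (
    StimulusSchedule,
    activation_time,
    apd,
    apd_map,
    detect_beats,
    detect_eads,
    isochrone_map,
    make_ap_trace,
)
from camapper.preprocess import PixelTrace, TissueMask


def _train(n_beats, pcl_ms, apd80=179.0, dt=4.0, t0=50.0):
    """Multi-beat normalized AP trace built from the synthetic template."""
    n = int((t0 + n_beats * pcl_ms + 200) / dt)
    v = np.zeros(n)
    for k in range(n_beats):
        tr, _ = make_ap_trace(apd80, t0 + k * pcl_ms, dt, n)
        v += tr.values
    return PixelTrace(v, dt, normalized=True)


class TestDetectBeats:
    def test_five_captured_beats(self):
        sched = StimulusSchedule.steady_pacing(500.0, 5, t0_ms=50.0)
        trace = _train(5, 500.0)
        beats = detect_beats(trace, sched, 0.5)
        assert len(beats) == 5
        assert all(b.captured for b in beats)

    def test_flat_trace_yields_nothing(self):
        assert detect_beats(PixelTrace(np.zeros(200), 4.0), None, 0.5) == []

    def test_sls_protocol_gives_32_beats(self):
        sched = StimulusSchedule.sls(s1_count=30, s1s1_ms=500.0,
                                     s1s2_ms=1000.0, s2s3_ms=500.0, t0_ms=50.0)
        dt = 4.0
        n = int((sched.stim_times_ms[-1] + 600) / dt)
        v = np.zeros(n)
        for s in sched.stim_times_ms:
            tr, _ = make_ap_trace(170.0, s, dt, n)
            v += tr.values
        beats = detect_beats(PixelTrace(v, dt, normalized=True), sched, 0.5)
        assert len(beats) == 32
        assert all(b.captured for b in beats)

    def test_windows_partition_without_overlap(self):
        beats = detect_beats(_train(4, 500.0), None, 0.5)
        for a, b in zip(beats[:-1], beats[1:]):
            assert a.window[1] == b.window[0]
        for b in beats:
            assert b.window[0] <= b.activation_time_ms < b.window[1]


class TestActivationTime:
    def test_step_edge(self):
        v = np.zeros(60)
        v[25:] = 1.0  # step between frames 24 and 25 -> edge near 100 ms
        trace = PixelTrace(v, 4.0, normalized=True)
        beat = detect_beats(trace, None, 0.5)[0]
        assert activation_time(trace, beat) == pytest.approx(100.0, abs=4.0)

    def test_logistic_upstroke_max_slope_point(self):
        t = np.arange(150) * 4.0
        v = expit((t - 200.0) / 6.0)
        trace = PixelTrace(v, 4.0, normalized=True)
        beat = detect_beats(trace, None, 0.5)[0]
        assert activation_time(trace, beat) == pytest.approx(200.0, abs=2.0)

    def test_time_shift_equivariance(self):
        base, _ = make_ap_trace(200.0, 100.0, 4.0, 150)
        shifted, _ = make_ap_trace(200.0, 148.0, 4.0, 150)  # 12-frame shift
        t1 = activation_time(base, detect_beats(base, None, 0.5)[0])
        t2 = activation_time(shifted, detect_beats(shifted, None, 0.5)[0])
        assert t2 - t1 == pytest.approx(48.0, abs=0.5)


class TestAPD:
    def _triangle(self):
        # instant rise at 100 ms, linear fall to 0 over 300 ms
        t = np.arange(150) * 4.0
        v = np.where((t >= 100) & (t <= 400), np.clip(1 - (t - 100) / 300.0, 0, 1), 0.0)
        return PixelTrace(v, 4.0, normalized=True)

    def test_linear_repolarization_chord_crossings(self):
        trace = self._triangle()
        beat = detect_beats(trace, None, 0.5)[0]
        assert apd(trace, beat, 0.8) == pytest.approx(240.0, abs=4.0)
        assert apd(trace, beat, 0.5) == pytest.approx(150.0, abs=4.0)

    def test_unrepolarized_flagged_as_nan(self):
        t = np.arange(100) * 4.0
        v = np.clip((t - 50) / 8.0, 0, 1)  # rises and never comes down
        trace = PixelTrace(v, 4.0, normalized=True)
        beat = detect_beats(trace, None, 0.5)[0]
        assert np.isnan(apd(trace, beat, 0.8))

    def test_template_truth_recovered_within_one_frame(self):
        for apd80 in (179.0, 200.0, 298.0):
            trace, truth = make_ap_trace(apd80, 100.0, 4.0, 200)
            beat = detect_beats(trace, None, 0.5)[0]
            assert apd(trace, beat, 0.8) == pytest.approx(truth["apd80_ms"], abs=4.0)

    def test_monotone_in_level(self):
        trace, _ = make_ap_trace(250.0, 100.0, 4.0, 200)
        beat = detect_beats(trace, None, 0.5)[0]
        values = [apd(trace, beat, lvl) for lvl in (0.3, 0.5, 0.8, 0.9)]
        assert values == sorted(values)

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(0.2, 5.0), offset=st.floats(-2.0, 2.0))
    def test_affine_invariance_of_apd_and_activation(self, scale, offset):
        trace, _ = make_ap_trace(220.0, 100.0, 4.0, 160)
        rescaled = PixelTrace(scale * trace.values + offset, 4.0, normalized=False)
        b1 = detect_beats(trace, None, 0.5)[0]
        # threshold on the raw rescaled trace must be in its own units
        thr_trace = PixelTrace((rescaled.values - offset) / scale, 4.0)
        b2 = detect_beats(thr_trace, None, 0.5)[0]
        b2.peak_value = scale * b2.peak_value + offset
        b2.diastolic_baseline = scale * b2.diastolic_baseline + offset
        assert apd(rescaled, b2, 0.8) == pytest.approx(apd(trace, b1, 0.8), abs=1e-6)
        assert activation_time(rescaled, b2) == pytest.approx(
            activation_time(trace, b1), abs=1e-6)

    def test_level_out_of_range(self):
        trace, _ = make_ap_trace(220.0, 100.0, 4.0, 160)
        beat = detect_beats(trace, None, 0.5)[0]
        with pytest.raises(ValueError):
            apd(trace, beat, 1.2)


class TestMaps:
    def test_apd_map_recovers_gradient(self, e4031_noiseless):
        vm, _, mask, truth = e4031_noiseless
        amap = apd_map(vm, mask, 1, 0.8, truth.schedule)
        err = np.abs(amap.values_ms - truth.apd80_ms)
        assert np.nanmax(err) <= 4.0
        # monotone base-to-apex gradient in the row means
        rows = np.nanmean(amap.values_ms, axis=1)
        assert np.all(np.diff(rows) < 0)

    def test_apd_map_masks_unrepolarized_and_missing(self, e4031_noiseless):
        vm, _, mask, truth = e4031_noiseless
        with pytest.raises(ValueError, match="out of range"):
            apd_map(vm, mask, 99, 0.8, truth.schedule)

    def test_isochrone_plane_wave_spacing(self, plane_wave_stack):
        mask = TissueMask(np.ones((8, 16), dtype=bool))
        imap = isochrone_map(plane_wave_stack, mask, 0)
        col_means = np.nanmean(imap.activation_ms, axis=0)
        steps = np.diff(col_means)
        assert np.allclose(steps, 0.7, atol=0.1)
        assert np.nanmin(imap.activation_ms) == 0.0

    def test_isochrone_simultaneous_activation_all_zero(self):
        from camapper import AcquisitionMeta, MovieStack

        trace, _ = make_ap_trace(200.0, 60.0, 4.0, 100)
        data = np.broadcast_to(trace.values[:, None, None], (100, 4, 4)).copy()
        stack = MovieStack(data, AcquisitionMeta(n_rows=4, n_cols=4))
        imap = isochrone_map(stack, TissueMask(np.ones((4, 4), bool)), 0)
        assert np.nanmax(np.abs(imap.activation_ms)) < 1e-9

    def test_isochrone_focal_source_monotone_with_distance(self, e4031_noiseless):
        vm, _, mask, truth = e4031_noiseless
        imap = isochrone_map(vm, mask, 1, truth.schedule)
        rel = truth.activation_ms - truth.activation_ms.min()
        assert np.nanmax(np.abs(imap.activation_ms - rel)) <= 2.0


class TestEADDetection:
    def test_smooth_repolarization_has_no_events(self):
        trace, _ = make_ap_trace(280.0, 60.0, 4.0, 160, tau_rep_ms=60.0)
        beat = detect_beats(trace, None, 0.5)[0]
        assert detect_eads(trace, beat) == []

    def test_injected_event_recovered(self):
        trace, truth = make_ap_trace(
            300.0, 60.0, 4.0, 160,
            ead={"enabled": True, "takeoff_level": 0.5, "amplitude_fraction": 0.2},
        )
        beat = detect_beats(trace, None, 0.5)[0]
        events = detect_eads(trace, beat)
        assert len(events) == 1
        ev = events[0]
        assert ev.amplitude_fraction == pytest.approx(
            truth["ead"]["amplitude_fraction"], abs=0.02)
        assert ev.takeoff_level == pytest.approx(truth["ead"]["takeoff_level"], abs=0.05)
        assert ev.takeoff_time_ms == pytest.approx(
            truth["ead"]["takeoff_time_ms"], abs=8.0)

    def test_subthreshold_bump_ignored(self):
        trace, _ = make_ap_trace(
            300.0, 60.0, 4.0, 160,
            ead={"enabled": True, "takeoff_level": 0.5, "amplitude_fraction": 0.02},
        )
        beat = detect_beats(trace, None, 0.5)[0]
        assert detect_eads(trace, beat, min_amplitude_fraction=0.05) == []

    def test_ead_not_split_into_extra_beat(self):
        trace, _ = make_ap_trace(
            300.0, 60.0, 4.0, 160,
            ead={"enabled": True, "takeoff_level": 0.3, "amplitude_fraction": 0.3},
        )
        assert len(detect_beats(trace, None, 0.5)) == 1
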