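import numpy as np
import pytest

from camapper import (
    detect_beats,
    detect_secondary_rise,
    fit_decay_tau,
    make_ap_trace,
    make_ca_trace,
    rise_latency,
    secondary_rise_amplitude,
    secondary_rise_map,
    segment_transients,
)
from camapper.ca_analysis import CaTransient, SecondaryRise
from camapper.preprocess import PixelTrace


def _beats(n=1, pcl=1000.0, apd=298.0, t0=100.0, dt=4.0, n_frames=250):
    v = np.zeros(n_frames)
    for k in range(n):
        tr, _ = make_ap_trace(apd, t0 + k * pcl, dt, n_frames)
        v += tr.values
    trace = PixelTrace(v, dt, normalized=True)
    return trace, detect_beats(trace, None, 0.5)


class TestSegmentTransients:
    def test_one_transient_per_beat_with_prompt_onset(self):
        dt, n = 4.0, 700
        vm = np.zeros(n)
        ca = np.zeros(n)
        for k in range(5):
            tr, _ = make_ap_trace(179.0, 100.0 + 500.0 * k, dt, n)
            vm += tr.values
            ctr, _ = make_ca_trace(100.0 + 500.0 * k, 10.0, 63.0,
                                   frame_interval_ms=dt, n_frames=n)
            ca += ctr.values
        beats = detect_beats(PixelTrace(vm, dt, normalized=True), None, 0.5)
        trans = segment_transients(PixelTrace(ca, dt, normalized=True), beats)
        assert len(trans) == 5
        for t, b in zip(trans, beats):
            assert 0.0 <= t.onset_time_ms - b.activation_time_ms <= 60.0

    def test_flat_ca_channel_yields_nothing(self):
        _, beats = _beats()
        assert segment_transients(PixelTrace(np.zeros(250), 4.0), beats) == []

    def test_peak_times_match_generator_truth(self):
        _, beats = _beats()
        ctr, truth = make_ca_trace(100.0, 10.0, 100.0, n_frames=250)
        trans = segment_transients(ctr, beats)
        assert trans[0].peak_time_ms == pytest.approx(truth["peak_time_ms"], abs=4.0)


class TestSecondaryRiseDetection:
    def test_monotone_decay_returns_none(self):
        _, beats = _beats()
        ctr, _ = make_ca_trace(100.0, 10.0, 100.0, n_frames=250)
        trans = segment_transients(ctr, beats)
        assert detect_secondary_rise(trans[0], ctr) is None

    def test_bump_window_located(self):
        _, beats = _beats()
        ctr, truth = make_ca_trace(100.0, 10.0, 100.0,
                                   bump={"amplitude_percent": 8.8}, n_frames=250)
        trans = segment_transients(ctr, beats)
        rise = detect_secondary_rise(trans[0], ctr)
        assert rise is not None
        assert rise.onset_ms < truth["bump_center_ms"] < rise.offset_ms
        assert rise.onset_ms == pytest.approx(truth["bump_center_ms"], abs=40.0)

    def test_bump_clipped_by_transient_end_still_returned(self):
        _, beats = _beats()
        ctr, _ = make_ca_trace(
            100.0, 10.0, 100.0,
            bump={"amplitude_percent": 12.0, "center_fraction_of_decay": 0.97},
            n_frames=250,
        )
        trans = segment_transients(ctr, beats)
        rise = detect_secondary_rise(trans[0], ctr)
        assert rise is not None
        assert rise.offset_ms <= trans[0].end_time_ms

    def test_map_zero_iff_no_rise(self, e4031_noiseless):
        vm, ca, mask, truth = e4031_noiseless
        rmap = secondary_rise_map(ca, vm, mask, 1, truth.schedule)
        has_rise = truth.rise_amplitude_percent > 0
        assert np.all(rmap[mask.include & ~has_rise] == 0.0)
        assert np.all(rmap[mask.include & has_rise] > 0.0)


class TestChordAmplitude:
    def _triangular_case(self):
        # linear decay 1.0 -> 0.0 over [200, 500] ms with a triangular bump
        # peaking +0.15 above the line at 350, between 300 and 400
        dt = 2.0
        t = np.arange(0, 600, dt)
        decay = np.clip((500.0 - t) / 300.0, 0.0, 1.0)
        decay[t < 200.0] = 1.0
        decay[t < 8.0] = 0.0  # rise edge
        bump = np.where(
            (t >= 300.0) & (t <= 400.0),
            0.15 * (1.0 - np.abs(t - 350.0) / 50.0),
            0.0,
        )
        trace = PixelTrace(decay + bump, dt, normalized=True)
        transient = CaTransient(8.0, 200.0, 500.0, peak_amplitude=1.0)
        rise = SecondaryRise(onset_ms=300.0, offset_ms=400.0, apex_ms=350.0)
        return trace, transient, rise

    def test_triangular_bump_is_exactly_its_height(self):
        trace, transient, rise = self._triangular_case()
        amp = secondary_rise_amplitude(transient, rise, trace)
        assert amp == pytest.approx(15.0, abs=1e-9)

    def test_scale_invariance(self):
        trace, transient, rise = self._triangular_case()
        scaled = PixelTrace(3.0 * trace.values, trace.frame_interval_ms)
        transient3 = CaTransient(8.0, 200.0, 500.0, peak_amplitude=3.0)
        assert secondary_rise_amplitude(transient3, rise, scaled) == pytest.approx(
            15.0, abs=1e-9)

    def test_degenerate_rise_is_zero(self):
        trace, transient, _ = self._triangular_case()
        rise = SecondaryRise(onset_ms=300.0, offset_ms=300.0, apex_ms=300.0)
        assert secondary_rise_amplitude(transient, rise, trace) == 0.0

    def test_rise_outside_decay_limb_rejected(self):
        trace, transient, _ = self._triangular_case()
        rise = SecondaryRise(onset_ms=100.0, offset_ms=400.0, apex_ms=350.0)
        with pytest.raises(ValueError):
            secondary_rise_amplitude(transient, rise, trace)


class TestSecondaryRiseMap:
    def test_regional_bump_recovered(self, e4031_noiseless):
        vm, ca, mask, truth = e4031_noiseless
        rmap = secondary_rise_map(ca, vm, mask, 1, truth.schedule)
        region = truth.rise_amplitude_percent > 0
        err = np.abs(rmap[region] - truth.rise_amplitude_percent[region])
        assert np.nanmax(err) <= 1.0
        assert np.nanmax(rmap[mask.include & ~region]) == 0.0

    def test_colocalizes_with_long_apd_region(self, e4031_noiseless):
        vm, ca, mask, truth = e4031_noiseless
        rmap = secondary_rise_map(ca, vm, mask, 1, truth.schedule)
        det = (rmap > np.nanmax(rmap) / 2) & mask.include
        region = truth.rise_amplitude_percent > 0
        jaccard = (det & region).sum() / (det | region).sum()
        assert jaccard >= 0.8

    def test_null_scenario_is_all_zero(self):
        from camapper import make_movie_pair, scenario_preset
        from camapper.preprocess import normalize_pixelwise, segment_tissue_mask

        sc = scenario_preset("e4031", grid=(12, 12), n_beats=2, noise_sd=0.0, seed=3)
        sc.drift_slope_per_s = 0.0
        sc.secondary_rise["amplitude_percent"] = 0.0
        vm_raw, ca_raw, truth = make_movie_pair(sc)
        mask = segment_tissue_mask(vm_raw, 0.2)
        rmap = secondary_rise_map(normalize_pixelwise(ca_raw),
                                  normalize_pixelwise(vm_raw), mask, 1,
                                  truth.schedule)
        assert np.nanmax(rmap) == 0.0


class TestTauFit:
    def test_pure_exponential_recovered_exactly(self):
        t = np.arange(0, 600, 4.0)
        trace = PixelTrace(np.concatenate([[0.0, 0.5], np.exp(-t / 120.0)]), 4.0)
        transient = CaTransient(0.0, 8.0, trace.times_ms[-1], 1.0)
        fit = fit_decay_tau(transient, trace)
        assert fit.converged
        assert abs(fit.tau_ms - 120.0) / 120.0 <= 1e-6

    def test_exponential_with_offset(self):
        t = np.arange(0, 500, 4.0)
        trace = PixelTrace(np.concatenate([[0.1, 0.5], 0.8 * np.exp(-t / 63.0) + 0.1]), 4.0)
        transient = CaTransient(0.0, 8.0, trace.times_ms[-1], 0.8, diastolic=0.1)
        fit = fit_decay_tau(transient, trace)
        assert fit.tau_ms == pytest.approx(63.0, abs=0.5)

    def test_monte_carlo_noise_recovery(self):
        rng = np.random.default_rng(11)
        t = np.arange(0, 500, 4.0)
        clean = 0.8 * np.exp(-t / 63.0) + 0.1
        errs = []
        for _ in range(100):
            y = np.concatenate([[0.1, 0.5], clean + rng.normal(0, 0.02, t.size)])
            trace = PixelTrace(y, 4.0)
            transient = CaTransient(0.0, 8.0, trace.times_ms[-1], 0.8, diastolic=0.1)
            errs.append(abs(fit_decay_tau(transient, trace).tau_ms - 63.0) / 63.0)
        assert np.median(errs) <= 0.05

    def test_generator_truth_recovered(self):
        _, beats = _beats()
        for tau in (63.0, 100.0, 205.0):
            ctr, truth = make_ca_trace(100.0, 10.0, tau, n_frames=300)
            trans = segment_transients(ctr, beats)
            fit = fit_decay_tau(trans[0], ctr)
            assert fit.converged
            assert fit.tau_ms == pytest.approx(truth["oracle_tau_ms"], abs=1.0)

    def test_too_few_samples_rejected(self):
        trace = PixelTrace(np.array([0.0, 1.0, 0.5, 0.3, 0.2]), 4.0)
        transient = CaTransient(0.0, 4.0, 16.0, 1.0)
        with pytest.raises(ValueError, match="fewer than 5"):
            fit_decay_tau(transient, trace)


class TestRiseLatency:
    def _sigmoid_pair(self, shift_ms):
        from scipy.special import expit

        t = np.arange(100) * 4.0
        vm = PixelTrace(expit((t - 150.0) / 6.0), 4.0, normalized=True)
        ca = PixelTrace(expit((t - 150.0 - shift_ms) / 6.0), 4.0, normalized=True)
        return vm, ca

    @pytest.mark.parametrize("shift, tol", [(12.0, 1.0), (-8.0, 1.0), (0.0, 0.5)])
    def test_shifted_upstrokes(self, shift, tol):
        vm, ca = self._sigmoid_pair(shift)
        lat = rise_latency(vm, ca, (0.0, 400.0), 0.1)
        assert lat == pytest.approx(shift, abs=tol)

    def test_no_crossing_rejected(self):
        vm, _ = self._sigmoid_pair(0.0)
        flat = PixelTrace(np.zeros(100), 4.0)
        with pytest.raises(ValueError):
            rise_latency(vm, flat, (0.0, 400.0), 0.1)
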