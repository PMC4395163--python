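import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camapper import (
    AcquisitionMeta,
    MovieStack,
    filter_spatiotemporal,
    normalize_pixelwise,
    remove_baseline_drift,
    segment_tissue_mask,
)
from camapper.preprocess import PixelTrace, TissueMask, zero_range_pixels


def _stack(data, polarity="up"):
    data = np.asarray(data, dtype=float)
    meta = AcquisitionMeta(n_rows=data.shape[1], n_cols=data.shape[2], polarity=polarity)
    return MovieStack(data, meta)


class TestNormalize:
    def test_affine_map_of_single_trace(self):
        stack = _stack(np.array([2.0, 4.0, 6.0]).reshape(3, 1, 1) * np.ones((3, 2, 2)))
        out = normalize_pixelwise(stack)
        np.testing.assert_allclose(out.data[:, 0, 0], [0.0, 0.5, 1.0])

    def test_down_polarity_inverted(self):
        stack = _stack(np.array([6.0, 4.0, 2.0]).reshape(3, 1, 1) * np.ones((3, 2, 2)),
                       polarity="down")
        out = normalize_pixelwise(stack)
        np.testing.assert_allclose(out.data[:, 0, 0], [0.0, 0.5, 1.0])
        assert out.meta.polarity == "up"

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 100.0), b=st.floats(-50.0, 50.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(20, 2, 2))
        out1 = normalize_pixelwise(_stack(base))
        out2 = normalize_pixelwise(_stack(a * base + b))
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        stack = _stack(rng.normal(size=(30, 3, 3)))
        once = normalize_pixelwise(stack)
        twice = normalize_pixelwise(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_zero_range_pixels_flagged_and_zeroed(self):
        data = np.zeros((10, 2, 2))
        data[:, 0, 0] = np.arange(10)
        stack = _stack(data)
        flags = zero_range_pixels(stack)
        assert not flags[0, 0] and flags[1, 1]
        out = normalize_pixelwise(stack)
        assert np.all(out.data[:, 1, 1] == 0.0)


class TestFilter:
    def test_identity_kernel(self):
        rng = np.random.default_rng(0)
        stack = _stack(rng.normal(size=(10, 4, 4)))
        out = filter_spatiotemporal(stack, 0, 1)
        np.testing.assert_array_equal(out.data, stack.data)

    def test_constant_movie_unchanged(self):
        stack = _stack(np.full((10, 5, 5), 3.7))
        out = filter_spatiotemporal(stack, 1, 3)
        np.testing.assert_allclose(out.data, 3.7)

    def test_temporal_impulse_spreads_to_thirds(self):
        data = np.zeros((9, 2, 2))
        data[4, 0, 0] = 1.0
        out = filter_spatiotemporal(_stack(data), 0, 3)
        np.testing.assert_allclose(out.data[3:6, 0, 0], [1 / 3, 1 / 3, 1 / 3])
        np.testing.assert_allclose(out.data[[2, 6], 0, 0], 0.0)

    def test_spatial_mean_preserved_per_frame(self):
        rng = np.random.default_rng(1)
        stack = _stack(rng.normal(size=(6, 12, 12)))
        out = filter_spatiotemporal(stack, 2, 1)
        np.testing.assert_allclose(out.data.mean(axis=(1, 2)),
                                   stack.data.mean(axis=(1, 2)), atol=1e-9)

    def test_masked_filtering_no_bleed_from_outside(self):
        data = np.zeros((4, 4, 4))
        data[:, 0, 0] = 100.0  # hot pixel outside the mask
        include = np.ones((4, 4), dtype=bool)
        include[0, 0] = False
        out = filter_spatiotemporal(_stack(data), 1, 1, TissueMask(include))
        assert np.all(out.data[:, include] == 0.0)

    def test_even_or_oversized_width_rejected(self):
        stack = _stack(np.zeros((6, 2, 2)))
        with pytest.raises(ValueError):
            filter_spatiotemporal(stack, 1, 2)
        with pytest.raises(ValueError):
            filter_spatiotemporal(stack, 1, 7)


class TestDriftRemoval:
    def _beat_train(self, n=1500, dt=4.0):
        t = np.arange(n) * dt
        v = np.zeros(n)
        centers = np.arange(100.0, n * dt - 400, 500.0) + 80.0
        for c in centers:
            v += np.exp(-0.5 * ((t - c) / 30.0) ** 2)
        dist = np.min(np.abs(t[:, None] - centers[None, :]), axis=1)
        return t, v, dist >= 150.0  # true diastole, away from any beat

    def test_linear_ramp_removed(self):
        t, v, diastole = self._beat_train()
        drifted = PixelTrace(v + 2e-4 * t, 4.0)
        out = remove_baseline_drift(drifted, 1200.0)
        assert np.all(np.abs(out.values[diastole]) <= 0.02)

    def test_near_identity_without_drift(self):
        _, v, _ = self._beat_train()
        out = remove_baseline_drift(PixelTrace(v, 4.0), 1200.0)
        assert np.max(np.abs(out.values - v)) <= 0.02

    def test_pure_ramp_goes_to_zero(self):
        t = np.arange(1000) * 4.0
        out = remove_baseline_drift(PixelTrace(1e-4 * t, 4.0), 1000.0)
        assert np.max(np.abs(out.values)) <= 0.02

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="window too short"):
            remove_baseline_drift(PixelTrace(np.zeros(100), 4.0), 4.0)


class TestTissueMask:
    def test_separates_signal_from_flat_region(self):
        rng = np.random.default_rng(5)
        data = np.zeros((40, 8, 8))
        data[:, :, :4] = rng.normal(size=(40, 8, 4)) + np.sin(
            np.arange(40) / 3)[:, None, None]
        mask = segment_tissue_mask(_stack(data), 0.2)
        assert mask.include[:, :4].all()
        assert not mask.include[:, 4:].any()

    def test_threshold_zero_keeps_all_live_pixels(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(20, 4, 4))
        data[:, 0, 0] = 5.0  # dead pixel: zero range
        mask = segment_tissue_mask(_stack(data), 0.0)
        assert mask.n_included == 15

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        stack = _stack(rng.normal(size=(30, 10, 10)) * rng.uniform(0.1, 2.0, (10, 10)))
        counts = [segment_tissue_mask(stack, thr).n_included
                  for thr in (0.0, 0.2, 0.5, 0.8, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            segment_tissue_mask(_stack(np.zeros((5, 2, 2))), 1.5)
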