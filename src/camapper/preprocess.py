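"""Raw movie conditioning: polarity correction, per-pixel normalization,
separable spatiotemporal smoothing, baseline-drift removal and tissue
masking.

The downstream landmark definitions (80% repolarization, calcium downslope)
all assume upward deflections on a [0, 1] scale, so normalization flips
"down"-polarity dyes and rescales each pixel to its own dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import (
    maximum_filter1d,
    minimum_filter1d,
    uniform_filter,
    uniform_filter1d,
)

from .io_and_config import AcquisitionMeta, MovieStack


@dataclass
class TissueMask:
    """Boolean inclusion grid over the movie's pixels."""

    include: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.n_included < 1:
            raise ValueError("mask must include at least 1 pixel")

    @property
    def n_included(self) -> int:
        return int(self.include.sum())


@dataclass
class PixelTrace:
    """A single pixel's time series with its acquisition context.

    ``times_ms`` is implicit: sample k sits at k * frame_interval_ms plus the
    optional ``t0_ms`` offset (used when a trace is a cut-out of a longer
    recording).
    """

    values: np.ndarray
    frame_interval_ms: float
    site: tuple[int, int] | None = None
    channel: str = "vm"
    normalized: bool = False
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.values.size) * self.frame_interval_ms

    def __len__(self) -> int:
        return self.values.size


def pixel_trace(stack: MovieStack, row: int, col: int, normalized: bool | None = None) -> PixelTrace:
    """Extract one pixel's trace from a movie stack."""
    return PixelTrace(
        stack.data[:, row, col].copy(),
        stack.meta.frame_interval_ms,
        site=(row, col),
        channel=stack.meta.channel,
        normalized=bool(normalized) if normalized is not None else False,
    )


def zero_range_pixels(stack: MovieStack) -> np.ndarray:
    """Boolean grid of pixels with no dynamic range (dead sensor areas)."""
    rng = stack.data.max(axis=0) - stack.data.min(axis=0)
    return rng == 0


def normalize_pixelwise(stack: MovieStack) -> MovieStack:
    """Polarity-correct and min-max normalize each pixel to [0, 1].

    "Down"-polarity channels are inverted first so depolarization / Ca
    release always points up.  Pixels with zero dynamic range are set to 0
    everywhere (they are also excluded later by the tissue mask).
    Normalization is idempotent and invariant to per-pixel affine maps of the
    raw data.
    """
    data = stack.data
    if stack.meta.polarity == "down":
        data = -data
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    rng = hi - lo
    flat = rng == 0
    safe = np.where(flat, 1.0, rng)
    out = (data - lo) / safe
    out[:, flat] = 0.0
    meta = replace(stack.meta, polarity="up")
    return MovieStack(out, meta)


def filter_spatiotemporal(
    stack: MovieStack,
    spatial_radius_px: int = 1,
    temporal_width_frames: int = 3,
    mask: TissueMask | None = None,
) -> MovieStack:
    """Separable boxcar smoothing: spatial (per frame), then temporal.

    Boundaries use reflection, which for a uniform kernel conserves each
    frame's total (and hence mean) exactly.  With a partial tissue mask the
    spatial kernel is renormalized over included pixels only, so signal never
    bleeds in from outside the tissue.  Radius 0 / width 1 is the identity.
    """
    if temporal_width_frames < 1 or temporal_width_frames % 2 == 0:
        raise ValueError("temporal_width_frames must be an odd integer >= 1")
    if temporal_width_frames > stack.n_frames:
        raise ValueError("temporal_width_frames exceeds frame count")
    if spatial_radius_px < 0:
        raise ValueError("spatial_radius_px must be >= 0")

    data = stack.data
    if spatial_radius_px > 0:
        size = 2 * spatial_radius_px + 1
        if mask is None:
            data = uniform_filter(data, size=(1, size, size), mode="reflect")
        else:
            m = mask.include.astype(float)
            num = uniform_filter(data * m[None], size=(1, size, size), mode="reflect")
            den = uniform_filter(m, size=size, mode="reflect")
            with np.errstate(invalid="ignore", divide="ignore"):
                data = np.where(den[None] > 0, num / den[None], 0.0)
            data = np.where(mask.include[None], data, stack.data)
    if temporal_width_frames > 1:
        data = uniform_filter1d(data, size=temporal_width_frames, axis=0, mode="reflect")
    return MovieStack(data, stack.meta)


def remove_baseline_drift(trace: PixelTrace, window_ms: float) -> PixelTrace:
    """Subtract a rolling-minimum-then-smooth baseline estimate.

    The baseline is a morphological opening (rolling minimum then rolling
    maximum over ``window_ms``) followed by a smoothing average: the opening
    deletes beats narrower than the window while following any slow trend
    exactly (a pure ramp is its own opening), so subtracting it leaves the
    diastolic level near 0 without the half-window lag a bare rolling
    minimum would introduce.  The window must span at least two pacing
    cycles so every window sees true diastole.
    """
    n_win = int(round(window_ms / trace.frame_interval_ms))
    if n_win < 3:
        raise ValueError("drift window too short: must span >= 3 frames")
    n_win = min(n_win, len(trace))
    floor = minimum_filter1d(trace.values, size=n_win, mode="nearest")
    opened = maximum_filter1d(floor, size=n_win, mode="nearest")
    # the opening is biased in the first/last half-window (the morphological
    # filters see a truncated neighborhood there); replace those zones with
    # the linear trend of the adjacent interior
    h = n_win // 2
    n = opened.size
    if h >= 2 and n > 4 * h:
        idx = np.arange(n, dtype=float)
        c0 = np.polyfit(idx[h:3 * h], opened[h:3 * h], 1)
        opened[:h] = np.polyval(c0, idx[:h])
        c1 = np.polyfit(idx[n - 3 * h:n - h], opened[n - 3 * h:n - h], 1)
        opened[n - h:] = np.polyval(c1, idx[n - h:])
    baseline = uniform_filter1d(opened, size=max(3, n_win // 4), mode="nearest")
    out = trace.values - baseline
    return replace(trace, values=out, normalized=False)


def segment_tissue_mask(stack: MovieStack, amplitude_threshold: float = 0.2) -> TissueMask:
    """Mask in pixels whose raw dynamic range clears a robust movie-wide bar.

    A pixel is included iff its pre-normalization range exceeds
    ``amplitude_threshold`` times the 95th percentile of all pixel ranges.
    Zero-range (dead) pixels are always excluded.  ``threshold == 0`` keeps
    every live pixel; the included count is non-increasing in the threshold.
    """
    if not (0.0 <= amplitude_threshold <= 1.0):
        raise ValueError("amplitude_threshold must lie in [0, 1]")
    rng = stack.data.max(axis=0) - stack.data.min(axis=0)
    robust = float(np.percentile(rng, 95))
    include = (rng >= amplitude_threshold * robust) & (rng > 0)
    return TissueMask(include)
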