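"""Action-potential analysis on normalized Vm traces and movies.

Per-pixel beat segmentation by threshold crossing, activation time as the
maximum-upstroke-slope instant (sub-frame via quadratic interpolation), APD
at a configurable repolarization level (default 80%, i.e. APD80) with linear
interpolation between bracketing samples, per-beat APD and activation
isochrone maps, and early-afterdepolarization (EAD) detection on the
repolarization limb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_and_config import MovieStack, StimulusSchedule
from .preprocess import PixelTrace, TissueMask, pixel_trace


@dataclass
class Beat:
    """One detected action potential on a single pixel's trace.

    The window is half-open ``[start_ms, end_ms)``; consecutive beat windows
    partition the detection region without overlap.  ``captured`` marks beats
    whose upstroke follows a stimulus within the capture window.
    """

    activation_time_ms: float
    upstroke_peak_frame: int
    peak_value: float
    diastolic_baseline: float
    window: tuple[float, float]
    captured: bool = False

    @property
    def amplitude(self) -> float:
        return self.peak_value - self.diastolic_baseline


@dataclass
class APDMap:
    """Per-pixel action potential duration (ms) for one beat; NaN = masked."""

    values_ms: np.ndarray
    level: float = 0.8
    beat_index: int = 0
    pcl_ms: float | None = None


@dataclass
class IsochroneMap:
    """Per-pixel activation time (ms) relative to the earliest activated
    pixel of the beat; the minimum over the mask is 0."""

    activation_ms: np.ndarray
    beat_index: int = 0


@dataclass
class EADEvent:
    """A secondary depolarization during repolarization.

    ``takeoff_level`` is the normalized Vm at the local minimum from which
    the re-depolarization takes off; ``amplitude_fraction`` is the height of
    the secondary rise as a fraction of the beat's AP amplitude.
    """

    site: tuple[int, int] | None
    takeoff_time_ms: float
    takeoff_level: float
    amplitude_fraction: float
    beat_index: int = 0


# ---------------------------------------------------------------------------

_LEAD_MS = 40.0  # pre-upstroke context included in each beat window


def detect_beats(
    trace: PixelTrace,
    schedule: StimulusSchedule | None = None,
    threshold: float = 0.5,
    capture_window_ms: float = 50.0,
) -> list[Beat]:
    """Segment a normalized trace into beats by threshold crossing.

    A beat is a maximal interval in which the trace crosses ``threshold``
    upward and later returns below it, with hysteresis: after a beat the
    detector re-arms only once the trace has returned near diastole
    (``rearm_level``), so a secondary depolarization (EAD) that pokes back
    above the threshold mid-repolarization is not split off as a new beat.
    Beat windows include a short pre-upstroke lead (for the diastolic
    baseline) and run to the next beat's lead, so they tile the recording
    without overlap.  A beat is ``captured`` iff its upward crossing falls
    within ``capture_window_ms`` after some stimulus.  Returns an empty list
    when nothing crosses.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    rearm_level = 0.1
    v = trace.values
    dt = trace.frame_interval_ms
    above = v >= threshold
    cand = np.flatnonzero(~above[:-1] & above[1:]) + 1   # first index at/above
    downs = np.flatnonzero(above[:-1] & ~above[1:]) + 1  # first index below
    beats: list[Beat] = []
    if cand.size == 0:
        return beats
    ups_list = [int(cand[0])]
    for u in cand[1:]:
        if v[ups_list[-1]:u].min() < rearm_level:
            ups_list.append(int(u))
    ups = np.asarray(ups_list)

    starts: list[int] = []
    for k, up in enumerate(ups):
        if k == 0:
            lead = min(_LEAD_MS / dt, up)
        else:
            lead = min(_LEAD_MS / dt, (up - ups[k - 1]) / 2)
        starts.append(int(up - int(round(lead))))
    bounds = starts + [v.size]

    stim = np.asarray(schedule.stim_times_ms) if schedule is not None else None
    for k, up in enumerate(ups):
        i0, i1 = bounds[k], bounds[k + 1]
        after = downs[downs > up]
        down = int(after[0]) if after.size and after[0] < i1 else i1
        seg = v[up:down] if down > up else v[up:up + 1]
        peak_rel = int(np.argmax(seg))
        peak_idx = up + peak_rel
        pre = v[i0:up + 1]
        baseline = float(pre.min()) if pre.size else float(v[up])
        peak_val = float(v[peak_idx])
        if peak_val <= baseline:
            continue
        up_time = trace.t0_ms + up * dt
        captured = False
        if stim is not None and stim.size:
            lag = up_time - stim
            captured = bool(np.any((lag >= 0) & (lag <= capture_window_ms)))
        beat = Beat(
            activation_time_ms=np.nan,
            upstroke_peak_frame=peak_idx,
            peak_value=peak_val,
            diastolic_baseline=baseline,
            window=(trace.t0_ms + i0 * dt, trace.t0_ms + i1 * dt),
            captured=captured,
        )
        beat.activation_time_ms = activation_time(trace, beat)
        beats.append(beat)
    return beats


def activation_time(trace: PixelTrace, beat: Beat) -> float:
    """Time of maximum upstroke slope, refined to sub-frame precision.

    The discrete first difference is maximized over the beat's upstroke
    region (window start to the AP peak); a quadratic through the maximum and
    its neighbors refines the location to sub-frame precision.  Equivariant
    to time shifts and invariant to affine rescaling of the signal.  The
    attainable sub-frame precision is set by how many samples the upstroke
    spans: an upstroke much faster than the frame interval localizes to a
    fraction of a frame only.
    """
    dt = trace.frame_interval_ms
    i0 = max(0, int(round((beat.window[0] - trace.t0_ms) / dt)))
    i1 = beat.upstroke_peak_frame
    if i1 <= i0:
        i1 = min(i0 + 1, len(trace) - 1)
    seg = trace.values[i0:i1 + 1]
    if not np.all(np.isfinite(seg)):
        raise ValueError("non-finite values in upstroke window")
    d = np.diff(seg)
    if d.size == 0:
        return trace.t0_ms + i0 * dt
    j = int(np.argmax(d))
    # first difference d[j] sits between samples j and j+1
    frac = 0.0
    if 0 < j < d.size - 1:
        denom = d[j - 1] - 2 * d[j] + d[j + 1]
        if denom != 0:
            frac = float(np.clip(0.5 * (d[j - 1] - d[j + 1]) / denom, -0.5, 0.5))
    return trace.t0_ms + (i0 + j + 0.5 + frac) * dt


def apd(trace: PixelTrace, beat: Beat, level: float = 0.8) -> float:
    """Action potential duration at a repolarization level (0.8 = APD80).

    The repolarization threshold is ``peak - level * amplitude``.  APD is the
    first time after the AP peak at which the trace falls below that
    threshold and stays below for at least 2 frames (guarding against noise
    blips), linearly interpolated between the bracketing samples, minus the
    activation time.  Returns NaN when repolarization is not reached before
    the beat window ends (the "unrepolarized" flag).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("repolarization level out of range (0, 1)")
    v = trace.values
    dt = trace.frame_interval_ms
    thr = beat.peak_value - level * beat.amplitude
    i_end = min(len(trace), int(round((beat.window[1] - trace.t0_ms) / dt)))
    i = beat.upstroke_peak_frame
    while i + 1 < i_end:
        if v[i] >= thr > v[i + 1]:
            below2 = v[i + 2] < thr if i + 2 < i_end else True
            if below2:
                t_cross = trace.t0_ms + (i + (v[i] - thr) / (v[i] - v[i + 1])) * dt
                return float(t_cross - beat.activation_time_ms)
        i += 1
    return float("nan")


def _per_pixel_beats(
    vm: MovieStack,
    mask: TissueMask,
    schedule: StimulusSchedule | None,
    threshold: float,
):
    norm = vm  # caller supplies a normalized stack
    rows, cols = np.nonzero(mask.include)
    for r, c in zip(rows, cols):
        tr = pixel_trace(norm, int(r), int(c), normalized=True)
        yield (int(r), int(c)), tr, detect_beats(tr, schedule, threshold)


def apd_map(
    vm: MovieStack,
    mask: TissueMask,
    beat_index: int = 0,
    level: float = 0.8,
    schedule: StimulusSchedule | None = None,
    threshold: float = 0.5,
) -> APDMap:
    """Per-pixel APD for one beat over the tissue mask.

    Pixels where beat detection fails, the indexed beat does not exist, or
    repolarization is not reached ("unrepolarized") are masked (NaN) rather
    than extrapolated.
    """
    out = np.full((vm.meta.n_rows, vm.meta.n_cols), np.nan)
    any_ok = False
    for (r, c), tr, beats in _per_pixel_beats(vm, mask, schedule, threshold):
        if beat_index < len(beats):
            any_ok = True
            out[r, c] = apd(tr, beats[beat_index], level)
    if not any_ok:
        raise ValueError(f"beat_index {beat_index} out of range for every masked pixel")
    pcl = schedule.pcl_ms if schedule is not None else None
    return APDMap(out, level=level, beat_index=beat_index, pcl_ms=pcl)


def isochrone_map(
    vm: MovieStack,
    mask: TissueMask,
    beat_index: int = 0,
    schedule: StimulusSchedule | None = None,
    threshold: float = 0.5,
) -> IsochroneMap:
    """Activation isochrones: per-pixel activation time of one beat, relative
    to the earliest activated masked pixel."""
    out = np.full((vm.meta.n_rows, vm.meta.n_cols), np.nan)
    for (r, c), tr, beats in _per_pixel_beats(vm, mask, schedule, threshold):
        if beat_index < len(beats):
            out[r, c] = beats[beat_index].activation_time_ms
    if not np.any(np.isfinite(out)):
        raise ValueError(f"beat_index {beat_index} out of range for every masked pixel")
    out -= np.nanmin(out)
    return IsochroneMap(out, beat_index=beat_index)


def detect_eads(
    trace: PixelTrace,
    beat: Beat,
    min_amplitude_fraction: float = 0.05,
    takeoff_band: tuple[float, float] = (0.1, 0.9),
    beat_index: int = 0,
) -> list[EADEvent]:
    """Find early afterdepolarizations on a beat's repolarization limb.

    Between the AP peak and repolarization completion, a candidate takeoff is
    a local minimum where the smoothed first difference turns from negative
    to nonnegative while normalized Vm lies inside ``takeoff_band``.  An
    event is emitted iff the subsequent rise reaches at least
    ``min_amplitude_fraction`` of the AP amplitude before the next descent.
    Events are ordered by takeoff time; an empty list means a smooth
    monotone repolarization.
    """
    lo, hi = takeoff_band
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("takeoff_band must satisfy 0 < low < high < 1")
    v = trace.values
    dt = trace.frame_interval_ms
    amp = beat.amplitude
    vn = (v - beat.diastolic_baseline) / amp  # normalized to AP amplitude
    i_end = min(len(trace), int(round((beat.window[1] - trace.t0_ms) / dt)))
    # repolarization completes when vn falls below the takeoff band floor
    i_rep = i_end
    for i in range(beat.upstroke_peak_frame, i_end):
        if vn[i] < lo:
            i_rep = i
            break
    seg = vn[beat.upstroke_peak_frame:i_rep + 1]
    if seg.size < 4:
        return []
    d = np.diff(seg)
    if d.size >= 3:
        d = np.convolve(d, np.ones(3) / 3, mode="same")
    events: list[EADEvent] = []
    i = 1
    while i < d.size:
        if d[i - 1] < 0 <= d[i] and lo < seg[i] < hi:
            k0 = i - 1 + int(np.argmin(seg[i - 1:i + 2]))
            # follow the rise until the smoothed slope turns negative again
            j = i
            while j < d.size and d[j] >= 0:
                j += 1
            rise = float(seg[k0:j + 1].max() - seg[k0])
            if rise >= min_amplitude_fraction:
                events.append(
                    EADEvent(
                        site=trace.site,
                        takeoff_time_ms=trace.t0_ms + (beat.upstroke_peak_frame + k0) * dt,
                        takeoff_level=float(seg[k0]),
                        amplitude_fraction=min(rise, 1.0),
                        beat_index=beat_index,
                    )
                )
            i = j + 1
        else:
            i += 1
    return events
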