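"""Intracellular calcium transient analysis.

Pairs Ca_i transients with the co-registered pixel's Vm beats, detects the
secondary Ca_i rise (a spontaneous increase on the downslope of the primary
transient) and quantifies it as the largest deviation above the chord joining
the rise's onset and offset, expressed as a percent of the transient's peak
amplitude.  Also fits the monoexponential decay time constant (tau) and
measures the Ca-vs-Vm rise latency used to identify Ca_i pre-fluorescence at
EAD initiation sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .ap_analysis import Beat, detect_beats
from .io_and_config import MovieStack, StimulusSchedule
from .preprocess import PixelTrace, TissueMask, pixel_trace


@dataclass
class CaTransient:
    """One calcium transient tied to a Vm beat at the same pixel."""

    onset_time_ms: float
    peak_time_ms: float
    end_time_ms: float
    peak_amplitude: float
    beat_index: int = 0
    site: tuple[int, int] | None = None
    diastolic: float = 0.0

    def __post_init__(self) -> None:
        if not (self.onset_time_ms < self.peak_time_ms < self.end_time_ms):
            raise ValueError("transient requires onset < peak < end")
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be positive")


@dataclass
class SecondaryRise:
    """A secondary Ca_i rise on the decay limb of a transient.

    ``amplitude_percent`` is the largest deviation of the trace above the
    onset-offset chord, as a percent of the transient's peak amplitude.
    """

    onset_ms: float
    offset_ms: float
    apex_ms: float
    amplitude_percent: float = 0.0


@dataclass
class TauFit:
    """Monoexponential decay fit y = A exp(-(t - t_peak)/tau) + C."""

    tau_ms: float
    fit_window: tuple[float, float]
    rmse: float
    converged: bool


# ---------------------------------------------------------------------------

def segment_transients(
    ca_trace: PixelTrace,
    beats: list[Beat],
    onset_fraction: float = 0.1,
) -> list[CaTransient]:
    """One Ca transient per captured Vm beat of the co-registered pixel.

    Onset is the first upward crossing of ``onset_fraction`` of the
    transient's amplitude after the beat's Vm activation; the peak is the
    maximum before the next beat; the end is the earlier of the next onset
    and the return to the onset level.  Beats with no calcium response yield
    no transient.
    """
    v = ca_trace.values
    dt = ca_trace.frame_interval_ms
    out: list[CaTransient] = []
    for bi, beat in enumerate(beats):
        i0 = max(0, int(round((beat.activation_time_ms - ca_trace.t0_ms) / dt)))
        i1 = min(len(ca_trace), int(round((beat.window[1] - ca_trace.t0_ms) / dt)))
        if i1 - i0 < 3:
            continue
        seg = v[i0:i1]
        base = float(seg.min())
        amp = float(seg.max()) - base
        if amp <= 0:
            continue
        thr = base + onset_fraction * amp
        rising = np.flatnonzero((seg[:-1] < thr) & (seg[1:] >= thr))
        if rising.size == 0:
            continue
        on = i0 + int(rising[0]) + 1
        peak = i0 + int(np.argmax(seg))
        if peak <= on:
            continue
        end = i1 - 1
        for j in range(peak + 1, i1):
            if v[j] <= thr:
                end = j
                break
        if end <= peak:
            continue
        out.append(
            CaTransient(
                onset_time_ms=ca_trace.t0_ms + on * dt,
                peak_time_ms=ca_trace.t0_ms + peak * dt,
                end_time_ms=ca_trace.t0_ms + end * dt,
                peak_amplitude=amp,
                beat_index=bi,
                site=ca_trace.site,
                diastolic=base,
            )
        )
    return out


def _index(trace: PixelTrace, t_ms: float) -> int:
    return int(round((t_ms - trace.t0_ms) / trace.frame_interval_ms))


def detect_secondary_rise(
    transient: CaTransient,
    trace: PixelTrace,
    slope_tolerance: float = 0.0,
) -> SecondaryRise | None:
    """Locate a secondary rise on the transient's decay limb, or None.

    Scanning the decay from just below the peak to the transient end, the
    rise begins where the smoothed slope (normalized units per ms) recovers
    to at least ``-slope_tolerance`` — i.e. the decay stalls or reverses.
    Onset is the last sample before the stall, offset the first later sample
    at which the trace falls back to the onset value (or the transient end if
    it never does), and the apex the point of largest deviation above the
    onset-offset chord.  A strictly monotone decay returns None.
    """
    v = trace.values
    dt = trace.frame_interval_ms
    i_pk = _index(trace, transient.peak_time_ms)
    i_end = min(_index(trace, transient.end_time_ms), len(trace) - 1)
    if i_end - i_pk < 3:
        return None
    # skip the rounded top of the transient where the slope is naturally ~0
    start = i_pk
    top = transient.diastolic + 0.95 * transient.peak_amplitude
    while start < i_end and v[start] > top:
        start += 1
    start = max(start, i_pk + 1)
    d = np.diff(v[i_pk:i_end + 1]) / dt
    if d.size >= 3:
        d = np.convolve(d, np.ones(3) / 3, mode="same")
    stall = None
    for j in range(start - i_pk, d.size):
        if d[j] >= -slope_tolerance:
            stall = i_pk + j
            break
    if stall is None:
        return None
    # anchor the onset at the local minimum around the stall: the trace is
    # flat there, so the chord anchor is insensitive to the sampling phase
    lo_i = max(i_pk + 1, stall - 1)
    hi_i = min(stall + 2, i_end)
    onset = lo_i + int(np.argmin(v[lo_i:hi_i + 1]))
    # offset: the return to the onset value, linearly interpolated between
    # the bracketing samples (or the transient end if it never returns)
    offset_t = trace.t0_ms + i_end * dt
    for j in range(onset + 2, i_end + 1):
        if v[j] <= v[onset]:
            frac = (v[j - 1] - v[onset]) / (v[j - 1] - v[j])
            offset_t = trace.t0_ms + (j - 1 + frac) * dt
            break
    rise = SecondaryRise(
        onset_ms=trace.t0_ms + onset * dt,
        offset_ms=float(offset_t),
        apex_ms=trace.t0_ms + onset * dt,
    )
    rise.amplitude_percent, rise.apex_ms = _chord_deviation(transient, rise, trace)
    return rise


def _chord_deviation(
    transient: CaTransient, rise: SecondaryRise, trace: PixelTrace
) -> tuple[float, float]:
    # offset_ms may sit between samples (interpolated return-to-onset time)
    v = trace.values
    times = trace.times_ms
    i_on = _index(trace, rise.onset_ms)
    j_hi = min(int(np.floor((rise.offset_ms - trace.t0_ms) / trace.frame_interval_ms)),
               len(trace) - 1)
    if j_hi <= i_on:
        return 0.0, rise.onset_ms
    y_off = float(np.interp(rise.offset_ms, times, v))
    t = times[i_on:j_hi + 1]
    seg = v[i_on:j_hi + 1]
    chord = np.interp(t, [times[i_on], rise.offset_ms], [seg[0], y_off])
    dev = seg - chord
    k = int(np.argmax(dev))
    pct = 100.0 * max(float(dev[k]), 0.0) / transient.peak_amplitude
    return pct, float(t[k])


def secondary_rise_amplitude(
    transient: CaTransient, rise: SecondaryRise, trace: PixelTrace
) -> float:
    """Largest deviation above the onset-offset chord, % of peak amplitude.

    The chord is the straight line between the trace values at the rise's
    onset and offset; the amplitude is the maximum of (trace - chord) over
    the rise window, divided by the transient's peak amplitude, times 100.
    Never negative, and invariant to affine rescaling of the raw trace.
    """
    i_pk = _index(trace, transient.peak_time_ms)
    i_end = _index(trace, transient.end_time_ms)
    i_on = _index(trace, rise.onset_ms)
    i_off = _index(trace, rise.offset_ms)
    if i_on < i_pk or i_off > i_end:
        raise ValueError("rise onset/offset outside the transient's decay limb")
    pct, _ = _chord_deviation(transient, rise, trace)
    return pct


def secondary_rise_map(
    ca: MovieStack,
    vm: MovieStack,
    mask: TissueMask,
    beat_index: int = 0,
    schedule: StimulusSchedule | None = None,
    threshold: float = 0.5,
    slope_tolerance: float = 0.0,
) -> np.ndarray:
    """Per-pixel secondary-rise amplitude (%) for one beat; 0 where no rise
    is detected, NaN outside the mask.  Vm and Ca stacks must be
    co-registered and normalized."""
    out = np.full((ca.meta.n_rows, ca.meta.n_cols), np.nan)
    rows, cols = np.nonzero(mask.include)
    any_ok = False
    for r, c in zip(rows, cols):
        vtr = pixel_trace(vm, int(r), int(c), normalized=True)
        ctr = pixel_trace(ca, int(r), int(c), normalized=True)
        beats = detect_beats(vtr, schedule, threshold)
        if beat_index >= len(beats):
            continue
        any_ok = True
        trans = [t for t in segment_transients(ctr, beats) if t.beat_index == beat_index]
        out[r, c] = 0.0
        if trans:
            rise = detect_secondary_rise(trans[0], ctr, slope_tolerance)
            if rise is not None:
                out[r, c] = rise.amplitude_percent
    if not any_ok:
        raise ValueError(f"beat_index {beat_index} invalid at every masked pixel")
    return out


def fit_decay_tau(
    transient: CaTransient,
    trace: PixelTrace,
    recovery_fraction: float = 0.9,
) -> TauFit:
    """Least-squares monoexponential fit to the transient's decay limb.

    Fits ``y(t) = A exp(-(t - t_peak)/tau) + C`` from the peak to
    ``recovery_fraction`` recovery toward the diastolic level (or the
    transient end, whichever comes first).  ``converged`` is False when the
    optimizer fails or tau exceeds 10x the window length.
    """
    v = trace.values
    i_pk = _index(trace, transient.peak_time_ms)
    i_end = min(_index(trace, transient.end_time_ms), len(trace) - 1)
    floor = transient.diastolic + (1.0 - recovery_fraction) * transient.peak_amplitude
    # landmarks (shoulder, 90%-recovery endpoint) come from a lightly
    # smoothed copy so single noise samples cannot truncate the window;
    # the fit itself uses raw values
    vs = np.convolve(v, np.ones(3) / 3, mode="same") if v.size >= 3 else v
    # shoulder guard: start once the trace has left the rounded top, where
    # the decay is not yet exponential (capped at 12 ms past the peak)
    start = i_pk
    top = transient.diastolic + 0.95 * transient.peak_amplitude
    cap = i_pk + max(1, int(round(12.0 / trace.frame_interval_ms)))
    while start < min(i_end, cap) and vs[start] > top:
        start += 1
    j = i_end
    for k in range(start + 1, i_end + 1):
        if vs[k] <= floor:
            j = k
            break
    if j - start + 1 < 5:
        raise ValueError("decay limb has fewer than 5 samples")
    t = trace.times_ms[start:j + 1] - trace.times_ms[start]
    y = v[start:j + 1]
    window = (float(trace.times_ms[start]), float(trace.times_ms[j]) + trace.frame_interval_ms)
    span = t[-1] - t[0]

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    a0 = max(float(y[0] - y[-1]), 1e-6)
    tau0 = max(span / 3.0, trace.frame_interval_ms)
    try:
        popt, _ = curve_fit(
            model, t, y, p0=(a0, tau0, float(y[-1])),
            bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return TauFit(float("nan"), window, float("nan"), False)
    resid = y - model(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    tau = float(popt[1])
    converged = bool(np.isfinite(tau) and tau <= 10.0 * span)
    return TauFit(tau, window, rmse, converged)


def rise_latency(
    vm_trace: PixelTrace,
    ca_trace: PixelTrace,
    window: tuple[float, float],
    rise_fraction: float = 0.1,
) -> float:
    """Ca-vs-Vm upstroke latency (ms) within a half-open time window.

    Each trace's crossing of ``rise_fraction`` of its local amplitude inside
    the window is found by linear interpolation; the latency is the Ca
    crossing minus the Vm crossing.  Negative latency = Ca_i
    pre-fluorescence (calcium rising before the local Vm upstroke), the
    signature of an EAD initiation site.
    """
    t_vm = _crossing_time(vm_trace, window, rise_fraction)
    t_ca = _crossing_time(ca_trace, window, rise_fraction)
    return float(t_ca - t_vm)


def _crossing_time(trace: PixelTrace, window: tuple[float, float], frac: float) -> float:
    t = trace.times_ms
    sel = (t >= window[0]) & (t < window[1])
    if sel.sum() < 2:
        raise ValueError("window spans fewer than 2 samples")
    seg = trace.values[sel]
    ts = t[sel]
    lo, hi = float(seg.min()), float(seg.max())
    if hi <= lo:
        raise ValueError("trace has no amplitude inside the window")
    thr = lo + frac * (hi - lo)
    idx = np.flatnonzero((seg[:-1] < thr) & (seg[1:] >= thr))
    if idx.size == 0:
        raise ValueError("trace does not cross the rise fraction inside the window")
    i = int(idx[0])
    return float(ts[i] + (thr - seg[i]) / (seg[i + 1] - seg[i]) * (ts[i + 1] - ts[i]))
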