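"""Pseudo-ECG derivation, arrhythmia episode classification and torsades de
pointes (TdP) inducibility tabulation.

The optical pseudo-ECG is the difference of regional mean Vm signals across a
split of the tissue mask — a global surrogate electrogram that turns
beat-to-beat changes in propagation direction into morphology changes.  TdP
is called operationally: a polymorphic ventricular tachycardia run of more
than 3 beats (i.e. at least 4), with polymorphism judged by the waveform
correlation of successive aligned beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .io_and_config import MovieStack, StimulusSchedule
from .preprocess import PixelTrace, TissueMask

CONDITIONS = ("baseline", "e4031", "ry_tg", "nifedipine")

_LABELS = ("no_arrhythmia", "single_ectopy", "monomorphic_vt", "tdp")


@dataclass
class EpisodeClassification:
    """Arrhythmia call for one recording.

    ``monomorphic_vt`` covers every fast run that is not TdP (including the
    rare polymorphic run of 3 or fewer beats, which fails the "more than 3
    beats" criterion).  ``label == "tdp"`` guarantees ``n_beats >= 4`` and
    a failed morphology-correlation criterion.
    """

    label: str
    n_beats: int = 0
    cycle_lengths_ms: list = field(default_factory=list)
    morphology_correlations: list = field(default_factory=list)
    induced_by: str = "none"

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}")
        if self.label == "tdp" and self.n_beats < 4:
            raise ValueError("tdp requires more than 3 beats")


@dataclass
class InducibilityTable:
    """Binary hearts x conditions matrix of TdP inducibility."""

    hearts: list
    conditions: tuple = CONDITIONS
    inducible: np.ndarray = None

    def __post_init__(self) -> None:
        self.inducible = np.asarray(self.inducible, dtype=int)
        if self.inducible.shape != (len(self.hearts), len(self.conditions)):
            raise ValueError("inducibility matrix shape mismatch")
        if not np.isin(self.inducible, (0, 1)).all():
            raise ValueError("inducibility entries must be 0/1")

    @property
    def counts(self) -> np.ndarray:
        return self.inducible.sum(axis=0)

    @property
    def percentages(self) -> np.ndarray:
        return np.round(100.0 * self.counts / len(self.hearts), 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.inducible, index=self.hearts, columns=list(self.conditions))

    def to_csv(self, path: str | Path) -> Path:
        df = self.to_frame()
        df.loc["percent"] = self.percentages
        df.to_csv(path, index_label="heart")
        return Path(path)


# ---------------------------------------------------------------------------

def derive_pseudo_ecg(
    vm: MovieStack,
    mask: TissueMask,
    split_axis: str = "col",
    split_position: int | None = None,
) -> PixelTrace:
    """Optical pseudo-ECG: mean Vm over region A minus mean over region B.

    A and B are the two halves of the tissue mask across a vertical
    (``split_axis="col"``, default) or horizontal (``"row"``) split.  A
    spatially uniform movie yields an identically zero trace; swapping A and
    B negates it.
    """
    if split_axis not in ("row", "col"):
        raise ValueError("split_axis must be 'row' or 'col'")
    axis_len = vm.meta.n_rows if split_axis == "row" else vm.meta.n_cols
    pos = axis_len // 2 if split_position is None else int(split_position)
    grid_r, grid_c = np.meshgrid(
        np.arange(vm.meta.n_rows), np.arange(vm.meta.n_cols), indexing="ij"
    )
    coord = grid_r if split_axis == "row" else grid_c
    a = mask.include & (coord < pos)
    b = mask.include & (coord >= pos)
    if not a.any() or not b.any():
        raise ValueError("pseudo-ECG split leaves an empty region")
    trace = vm.data[:, a].mean(axis=1) - vm.data[:, b].mean(axis=1)
    return PixelTrace(trace, vm.meta.frame_interval_ms, site=None, channel="vm")


def _deflection_times(pecg: PixelTrace, min_separation_ms: float = 60.0):
    """Beat times from the rectified, smoothed pseudo-ECG slope (scale-free).

    Working on |d(pECG)/dt| rather than |pECG| keeps the detector on the
    sharp depolarization deflections: the broad repolarization wave of each
    beat moves the pseudo-ECG just as far but far more slowly, so it stays
    below the relative height threshold instead of being double-counted as a
    beat.
    """
    v = uniform_filter1d(pecg.values,
                         size=max(3, int(round(8.0 / pecg.frame_interval_ms))))
    rect = np.abs(np.gradient(v, pecg.frame_interval_ms))
    rect = uniform_filter1d(rect, size=max(3, int(round(8.0 / pecg.frame_interval_ms))))
    top = float(rect.max())
    if top <= 0:
        return np.array([]), np.array([], dtype=int)
    dist = max(1, int(round(min_separation_ms / pecg.frame_interval_ms)))
    peaks, _ = find_peaks(rect, height=0.35 * top, distance=dist)
    return pecg.t0_ms + peaks * pecg.frame_interval_ms, peaks


def classify_episode(
    pecg: PixelTrace,
    intrinsic_cl_ms: float | None = None,
    vt_cl_fraction: float = 0.75,
    morphology_r_threshold: float = 0.8,
    schedule: StimulusSchedule | None = None,
) -> EpisodeClassification:
    """Classify a pseudo-ECG episode: no arrhythmia, ectopy, VT or TdP.

    Beats are deflections of the rectified smoothed trace.  A run is VT when
    at least 2 consecutive cycle lengths fall below ``vt_cl_fraction`` times
    the intrinsic (escape) cycle length, estimated from the pre-run segment
    when not supplied.  The run is polymorphic when the minimum correlation
    of successive peak-aligned beat waveforms is below
    ``morphology_r_threshold``; TdP is a polymorphic run of more than 3
    beats.  Invariant to amplitude scaling of the pseudo-ECG.
    """
    times, peak_idx = _deflection_times(pecg)
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        return EpisodeClassification("no_arrhythmia")
    cls = np.diff(times)
    if intrinsic_cl_ms is None:
        slow = cls[cls >= np.median(cls)]
        if slow.size == 0:
            raise ValueError("unmeasurable intrinsic cycle length")
        intrinsic_cl_ms = float(np.median(slow))
    fast = cls < vt_cl_fraction * intrinsic_cl_ms

    # longest run of consecutive fast cycle lengths
    best_start, best_len, cur_start, cur_len = 0, 0, 0, 0
    for i, f in enumerate(fast):
        if f:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0

    if best_len == 0:
        return EpisodeClassification("no_arrhythmia", n_beats=0, cycle_lengths_ms=list(cls))
    run_beats = best_len + 1  # n consecutive fast CLs span n+1 beats
    run_cls = list(cls[best_start:best_start + best_len])
    run_peaks = peak_idx[best_start:best_start + run_beats]

    induced_by = "spontaneous"
    if schedule is not None and len(schedule.stim_times_ms):
        t_run = times[best_start]
        lags = t_run - np.asarray(schedule.stim_times_ms)
        induced_by = "pacing" if np.any((lags >= 0) & (lags <= 2000.0)) else "spontaneous"

    corrs = _successive_correlations(pecg, run_peaks)
    polymorphic = bool(corrs) and min(corrs) < morphology_r_threshold

    if run_beats == 1:
        return EpisodeClassification(
            "single_ectopy", 1, run_cls, corrs, induced_by=induced_by)
    if best_len >= 2:  # >= 2 consecutive short CLs: ventricular tachycardia
        if polymorphic and run_beats > 3:
            label = "tdp"
        else:
            label = "monomorphic_vt"
    else:
        label = "single_ectopy"
    return EpisodeClassification(label, run_beats, run_cls, corrs, induced_by=induced_by)


def _successive_correlations(pecg: PixelTrace, peak_idx: np.ndarray) -> list[float]:
    """Pearson correlations of successive beat waveforms, peak-aligned."""
    v = pecg.values - np.median(pecg.values)
    if len(peak_idx) < 2:
        return []
    half = max(2, int(np.min(np.diff(peak_idx)) // 2))
    out: list[float] = []
    for p, q in zip(peak_idx[:-1], peak_idx[1:]):
        a = _window(v, p, half)
        b = _window(v, q, half)
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            out.append(1.0)
        else:
            out.append(float(np.corrcoef(a, b)[0, 1]))
    return out


def _window(v: np.ndarray, center: int, half: int) -> np.ndarray:
    pad_lo = max(0, half - center)
    pad_hi = max(0, center + half + 1 - v.size)
    seg = v[max(0, center - half):min(v.size, center + half + 1)]
    return np.pad(seg, (pad_lo, pad_hi))


def tabulate_inducibility(
    per_recording: list[tuple[object, str, EpisodeClassification]],
    hearts: list | None = None,
) -> tuple[InducibilityTable, pd.DataFrame]:
    """Collapse per-recording classifications into the hearts x conditions
    inducibility table plus a per-condition count/percent summary.

    A heart is inducible under a condition iff its recording there is TdP;
    spontaneous and pacing-induced episodes both count.  Each heart may
    appear at most once per condition (duplicates are an error).
    """
    seen: dict[tuple[object, str], int] = {}
    heart_order: list = list(hearts) if hearts is not None else []
    for heart, cond, epi in per_recording:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
        key = (heart, cond)
        if key in seen:
            raise ValueError(f"duplicate heart-condition pair: {key}")
        seen[key] = int(epi.label == "tdp")
        if hearts is None and heart not in heart_order:
            heart_order.append(heart)
    mat = np.zeros((len(heart_order), len(CONDITIONS)), dtype=int)
    for (heart, cond), val in seen.items():
        mat[heart_order.index(heart), CONDITIONS.index(cond)] = val
    table = InducibilityTable(heart_order, CONDITIONS, mat)
    summary = pd.DataFrame(
        {
            "condition": list(CONDITIONS),
            "n_inducible": table.counts,
            "n_hearts": len(heart_order),
            "percent": table.percentages,
        }
    )
    return table, summary
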