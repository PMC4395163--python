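"""Movie stacks, acquisition metadata, stimulus schedules, map I/O and run
configuration.

Conventions used throughout the package:

* arrays are indexed ``(frame, row, col)``, 0-based, pixel ``(0, 0)`` is the
  top-left corner of the field of view;
* the time of frame *k* is exactly ``k * frame_interval_ms`` (no cumulative
  drift);
* time windows are half-open ``[t_start, t_end)`` in milliseconds;
* 2-D maps are float arrays in which masked-out pixels are NaN; on disk they
  are CSV matrices with the sentinel token ``NA``.

Raw fluorescence is stored untouched by the readers; polarity correction and
normalization are the preprocessing stage's job.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("camapper")

_CHANNELS = ("vm", "cai")
_POLARITIES = ("up", "down")
_PROTOCOLS = ("steady_pacing", "sls", "burst", "none")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Camera geometry and channel conventions for one movie.

    Defaults mirror a typical dual-dye panoramic mapping rig: 4 ms/frame,
    128 x 128 pixels at 0.35 mm pitch.  ``polarity`` states whether
    depolarization (Vm) or Ca release (Ca_i) moves raw fluorescence up or
    down; voltage dyes commonly read out inverted.
    """

    frame_interval_ms: float = 4.0
    pixel_pitch_mm: float = 0.35
    n_rows: int = 128
    n_cols: int = 128
    channel: str = "vm"
    polarity: str = "up"

    def __post_init__(self) -> None:
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {_CHANNELS}")
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}")


@dataclass
class MovieStack:
    """One channel's fluorescence movie: ``data[frame, row, col]`` + metadata."""

    data: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("movie data must be 3-D (frame, row, col)")
        if self.data.shape[0] < 2:
            raise ValueError("movie must have at least 2 frames")
        if self.data.shape[1:] != (self.meta.n_rows, self.meta.n_cols):
            raise ValueError(
                f"frame grid {self.data.shape[1:]} does not match metadata "
                f"({self.meta.n_rows}, {self.meta.n_cols})"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Time of each frame; frame k is at exactly k * frame_interval_ms."""
        return np.arange(self.n_frames) * self.meta.frame_interval_ms

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.meta.frame_interval_ms


@dataclass(frozen=True)
class StimulusSchedule:
    """Pacing stimulus times with a protocol label.

    ``sls`` denotes the short-long-short S1/S2/S3 provocation sequence (a
    drive train, a long pause, then a premature extrastimulus); ``burst`` a
    rapid burst after a pause.
    """

    stim_times_ms: tuple = ()
    protocol_label: str = "none"
    pcl_ms: float | None = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.stim_times_ms)
        object.__setattr__(self, "stim_times_ms", times)
        if self.protocol_label not in _PROTOCOLS:
            raise ValueError(f"protocol_label must be one of {_PROTOCOLS}")
        if any(t < 0 for t in times):
            raise ValueError("stimulus times must be nonnegative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("stimulus times must be strictly increasing")
        if self.pcl_ms is not None and self.pcl_ms <= 0:
            raise ValueError("pcl_ms must be positive")

    @staticmethod
    def steady_pacing(pcl_ms: float, n_beats: int, t0_ms: float = 0.0) -> "StimulusSchedule":
        return StimulusSchedule(
            tuple(t0_ms + i * pcl_ms for i in range(n_beats)),
            "steady_pacing",
            pcl_ms,
        )

    @staticmethod
    def sls(
        s1_count: int = 30,
        s1s1_ms: float = 500.0,
        s1s2_ms: float = 1000.0,
        s2s3_ms: float = 500.0,
        t0_ms: float = 0.0,
    ) -> "StimulusSchedule":
        """S1/S2/S3 short-long-short protocol: S1 drive train, long S1-S2
        pause, premature S3."""
        s1 = [t0_ms + i * s1s1_ms for i in range(s1_count)]
        s2 = s1[-1] + s1s2_ms
        s3 = s2 + s2s3_ms
        return StimulusSchedule(tuple(s1 + [s2, s3]), "sls", s1s1_ms)


# ---------------------------------------------------------------------------
# Analysis configuration

_CONFIG_SPEC: dict[str, tuple[object, tuple[float, float] | None]] = {
    # key: (default, legal open range or None)
    "frame_interval_ms": (4.0, (0.0, float("inf"))),
    "pixel_pitch_mm": (0.35, (0.0, float("inf"))),
    "normalize.enabled": (True, None),
    "filter.spatial_radius_px": (1, None),
    "filter.temporal_width_frames": (3, None),
    "drift.window_ms": (2000.0, (0.0, float("inf"))),
    "mask.amplitude_threshold": (0.2, None),  # closed [0, 1], checked below
    "beat.threshold": (0.5, (0.0, 1.0)),
    "beat.capture_window_ms": (50.0, (0.0, float("inf"))),
    "repol_level": (0.8, (0.0, 1.0)),
    "ead.min_amplitude_fraction": (0.05, (0.0, 1.0)),
    "ead.takeoff_low": (0.1, (0.0, 1.0)),
    "ead.takeoff_high": (0.9, (0.0, 1.0)),
    "ca.onset_fraction": (0.1, (0.0, 1.0)),
    "ca.slope_tolerance": (0.0, None),
    "ca.tau_recovery_fraction": (0.9, (0.0, 1.0)),
    "tdp.vt_cl_fraction": (0.75, (0.0, 1.0)),
    "tdp.morphology_r_threshold": (0.8, (-1.0, 1.0)),
    "tdp.min_beats": (4, None),
    "seed": (0, None),
}


@dataclass
class AnalysisConfig:
    """Flat key-value bag of every downstream tunable, with validated defaults.

    Keys are dotted (``filter.spatial_radius_px``); unknown keys are rejected
    so that a typo in a config file fails loudly rather than silently using a
    default.
    """

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {k: v for k, (v, _) in _CONFIG_SPEC.items()}
        for key, val in self.values.items():
            if key not in _CONFIG_SPEC:
                raise KeyError(f"unknown config key: {key!r}")
            merged[key] = val
        _validate_config(merged)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    def get(self, key: str, default=None):
        return self.values.get(key, default)


def _validate_config(cfg: dict) -> None:
    for key, (_, rng) in _CONFIG_SPEC.items():
        val = cfg[key]
        if rng is not None:
            lo, hi = rng
            if not (lo < float(val) < hi):
                raise ValueError(f"config {key}={val!r} out of range ({lo}, {hi})")
    thr = float(cfg["mask.amplitude_threshold"])
    if not (0.0 <= thr <= 1.0):
        raise ValueError(f"config mask.amplitude_threshold={thr} out of range [0, 1]")
    if int(cfg["filter.temporal_width_frames"]) % 2 != 1:
        raise ValueError("filter.temporal_width_frames must be odd")
    if int(cfg["filter.spatial_radius_px"]) < 0:
        raise ValueError("filter.spatial_radius_px must be >= 0")
    if not cfg["ead.takeoff_low"] < cfg["ead.takeoff_high"]:
        raise ValueError("ead takeoff band must satisfy low < high")


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load a YAML config file; absent keys take documented defaults.

    Nested mappings are flattened to dotted keys, so both
    ``filter: {spatial_radius_px: 2}`` and ``filter.spatial_radius_px: 2``
    work.  The full effective configuration is echoed to the log.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a mapping")
            raw = _flatten(loaded)
    # "repol_level" accepted as an alias used in run configs
    cfg = AnalysisConfig(raw)
    for key in sorted(cfg.values):
        logger.info("config %s = %r", key, cfg.values[key])
    return cfg


def _flatten(d: dict, prefix: str = "") -> dict:
    out: dict = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, f"{key}."))
        else:
            out[key] = v
    return out


# ---------------------------------------------------------------------------
# Movie I/O

def read_movie_stack(path: str | Path, meta: AcquisitionMeta) -> MovieStack:
    """Read a movie from a multi-page TIFF (or ``.npy`` array container).

    Frames are returned in acquisition order with values untouched; the reader
    never normalizes.  All TIFF pages must share one 2-D shape matching the
    metadata grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            shapes = {page.shape for page in tf.pages}
            if len(shapes) != 1:
                raise ValueError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
            data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
    elif path.suffix.lower() == ".npy":
        data = np.load(path)
    else:
        raise ValueError(f"unsupported movie container: {path.suffix}")
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError("movie must contain at least 2 frames")
    if data.shape[1:] != (meta.n_rows, meta.n_cols):
        raise ValueError(
            f"movie grid {data.shape[1:]} does not match metadata grid "
            f"({meta.n_rows}, {meta.n_cols})"
        )
    return MovieStack(data.astype(float), meta)


def write_movie_stack(stack: MovieStack, path: str | Path) -> Path:
    """Write a movie as a multi-page float32 TIFF (or ``.npy``)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack.data.astype(np.float32))
    elif path.suffix.lower() == ".npy":
        np.save(path, stack.data)
    else:
        raise ValueError(f"unsupported movie container: {path.suffix}")
    return path


def read_meta_sidecar(path: str | Path) -> AcquisitionMeta:
    """Read an AcquisitionMeta from a YAML sidecar file."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return AcquisitionMeta(**d)


def write_meta_sidecar(meta: AcquisitionMeta, path: str | Path) -> Path:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(meta), fh)
    return Path(path)


# ---------------------------------------------------------------------------
# Map matrix I/O (CSV with NA sentinel for masked pixels)

def write_map_matrix(values: np.ndarray, path: str | Path) -> Path:
    """Write a 2-D map as a row-major CSV matrix; NaN pixels become ``NA``."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("map must be 2-D")
    path = Path(path)
    with open(path, "w") as fh:
        for row in values:
            fh.write(",".join("NA" if not np.isfinite(v) else repr(float(v)) for v in row))
            fh.write("\n")
    return path


def read_map_matrix(path: str | Path) -> np.ndarray:
    """Read a map CSV back; ``NA`` becomes NaN.  Inverse of write_map_matrix
    on finite values."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rows.append([np.nan if tok == "NA" else float(tok) for tok in line.split(",")])
    if not rows:
        raise ValueError(f"empty map file: {path}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"ragged map file: {path}")
    return np.array(rows, dtype=float)


def write_trace_table(
    times_ms: np.ndarray, traces: dict[str, np.ndarray], path: str | Path
) -> Path:
    """Write a trace table CSV: a time_ms column plus one column per site."""
    import pandas as pd

    df = pd.DataFrame({"time_ms": np.asarray(times_ms, dtype=float)})
    for name, vals in traces.items():
        df[name] = np.asarray(vals, dtype=float)
    df.to_csv(path, index=False)
    return Path(path)
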