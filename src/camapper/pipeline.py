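"""End-to-end orchestration: preprocess -> AP/Ca analysis -> maps -> episode
classification, as one reproducible run with a manifest.

A run either reads a Vm/Ca TIFF pair or generates a synthetic scenario, then
executes the stages in order, writing CSV maps and tables plus a JSON
manifest (config hash, input checksums, per-stage timings, output
checksums).  Deterministic stages are checksum-reproducible under a fixed
seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .ap_analysis import apd_map, detect_beats, isochrone_map
from .arrhythmia import classify_episode, derive_pseudo_ecg
from .ca_analysis import fit_decay_tau, secondary_rise_map, segment_transients
from .io_and_config import (
    AcquisitionMeta,
    AnalysisConfig,
    MovieStack,
    read_movie_stack,
    write_map_matrix,
)
from .preprocess import (
    filter_spatiotemporal,
    normalize_pixelwise,
    pixel_trace,
    segment_tissue_mask,
)
from .synthetic import SyntheticScenario, make_movie_pair


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    inputs: dict = field(default_factory=dict)    # name -> sha256
    outputs: dict = field(default_factory=dict)   # name -> sha256
    timings_s: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
        return Path(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    scenario: SyntheticScenario | None = None,
    vm_path: str | Path | None = None,
    ca_path: str | Path | None = None,
    meta: AcquisitionMeta | None = None,
) -> RunManifest:
    """Execute the full analysis on a movie pair and write all products.

    Inputs are either a ``SyntheticScenario`` (generated in memory) or paths
    to a Vm and a Ca movie with shared acquisition metadata.  Outputs:
    ``apd_map.csv``, ``isochrone_map.csv``, ``rise_map.csv``, ``tau.csv``,
    ``episode.json`` and ``manifest.json`` in ``out_dir``.  Any stage failure
    aborts with a stage-tagged error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    cfg_blob = json.dumps(config.values, sort_keys=True, default=str).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_blob).hexdigest(),
        seed=int(config["seed"]),
        version=__version__,
    )
    t_all = time.perf_counter()

    # --- acquire ----------------------------------------------------------
    t0 = time.perf_counter()
    schedule = None
    try:
        if scenario is not None:
            vm_raw, ca_raw, truth = make_movie_pair(scenario)
            schedule = truth.schedule
            manifest.inputs["scenario"] = hashlib.sha256(
                json.dumps(asdict(scenario), sort_keys=True, default=str).encode()
            ).hexdigest()
        else:
            if vm_path is None or ca_path is None or meta is None:
                raise ValueError("need either a scenario or vm/ca paths with metadata")
            from dataclasses import replace

            vm_raw = read_movie_stack(vm_path, replace(meta, channel="vm", polarity=meta.polarity))
            ca_raw = read_movie_stack(ca_path, replace(meta, channel="cai", polarity="up"))
            manifest.inputs[str(vm_path)] = _sha256(Path(vm_path))
            manifest.inputs[str(ca_path)] = _sha256(Path(ca_path))
    except Exception as exc:  # surface the offending stage and file
        raise StageError("read", str(exc)) from exc
    manifest.timings_s["acquire"] = time.perf_counter() - t0

    # --- preprocess -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        mask = segment_tissue_mask(vm_raw, float(config["mask.amplitude_threshold"]))
        vm = normalize_pixelwise(vm_raw)
        ca = normalize_pixelwise(ca_raw)
        radius = int(config["filter.spatial_radius_px"])
        width = int(config["filter.temporal_width_frames"])
        vm = filter_spatiotemporal(vm, radius, width, mask)
        ca = filter_spatiotemporal(ca, radius, width, mask)
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc
    manifest.timings_s["preprocess"] = time.perf_counter() - t0

    # --- AP analysis ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        beat_index = 1 if schedule is not None and len(schedule.stim_times_ms) > 1 else 0
        level = float(config["repol_level"])
        thr = float(config["beat.threshold"])
        amap = apd_map(vm, mask, beat_index, level, schedule, thr)
        imap = isochrone_map(vm, mask, beat_index, schedule, thr)
        write_map_matrix(amap.values_ms, out_dir / "apd_map.csv")
        write_map_matrix(imap.activation_ms, out_dir / "isochrone_map.csv")
    except Exception as exc:
        raise StageError("ap_analysis", str(exc)) from exc
    manifest.timings_s["ap_analysis"] = time.perf_counter() - t0

    # --- Ca analysis ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        rmap = secondary_rise_map(ca, vm, mask, beat_index, schedule, thr,
                                  float(config["ca.slope_tolerance"]))
        write_map_matrix(rmap, out_dir / "rise_map.csv")
        taus = _tau_table(vm, ca, mask, schedule, thr, config)
        with open(out_dir / "tau.csv", "w") as fh:
            fh.write("row,col,tau_ms,rmse,converged\n")
            for row in taus:
                fh.write(",".join(str(x) for x in row) + "\n")
    except Exception as exc:
        raise StageError("ca_analysis", str(exc)) from exc
    manifest.timings_s["ca_analysis"] = time.perf_counter() - t0

    # --- arrhythmia -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        pecg = derive_pseudo_ecg(vm, mask)
        episode = classify_episode(
            pecg,
            intrinsic_cl_ms=schedule.pcl_ms if schedule is not None else None,
            vt_cl_fraction=float(config["tdp.vt_cl_fraction"]),
            morphology_r_threshold=float(config["tdp.morphology_r_threshold"]),
            schedule=schedule,
        )
        with open(out_dir / "episode.json", "w") as fh:
            json.dump(asdict(episode), fh, indent=2)
    except Exception as exc:
        raise StageError("arrhythmia", str(exc)) from exc
    manifest.timings_s["arrhythmia"] = time.perf_counter() - t0

    for name in ("apd_map.csv", "isochrone_map.csv", "rise_map.csv", "tau.csv",
                 "episode.json"):
        manifest.outputs[name] = _sha256(out_dir / name)
    manifest.summary = {
        "apd_median_ms": float(np.nanmedian(amap.values_ms)),
        "rise_max_percent": float(np.nanmax(rmap)),
        "episode_label": episode.label,
        "n_masked_pixels": mask.n_included,
    }
    manifest.timings_s["total"] = time.perf_counter() - t_all
    manifest.write(out_dir / "manifest.json")
    return manifest


def _tau_table(vm, ca, mask, schedule, thr, config, max_sites: int = 16):
    """Decay-tau fits on a coarse grid of masked pixels."""
    rows, cols = np.nonzero(mask.include)
    step = max(1, len(rows) // max_sites)
    out = []
    for r, c in list(zip(rows, cols))[::step][:max_sites]:
        vtr = pixel_trace(vm, int(r), int(c), normalized=True)
        ctr = pixel_trace(ca, int(r), int(c), normalized=True)
        beats = detect_beats(vtr, schedule, thr)
        trans = segment_transients(ctr, beats, float(config["ca.onset_fraction"]))
        if not trans:
            continue
        try:
            fit = fit_decay_tau(trans[0], ctr, float(config["ca.tau_recovery_fraction"]))
        except ValueError:
            continue
        out.append((int(r), int(c), round(fit.tau_ms, 3), round(fit.rmse, 6),
                    fit.converged))
    return out
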