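import numpy as np
import pytest

from camapper import (
    AcquisitionMeta,
    MovieStack,
    make_ap_trace,
    make_movie_pair,
    scenario_preset,
)
from camapper.preprocess import normalize_pixelwise, segment_tissue_mask


@pytest.fixture(scope="session")
def e4031_noiseless():
    """Small noiseless E4031-like movie pair with ground truth, preprocessed."""
    sc = scenario_preset("e4031", grid=(32, 32), n_beats=3, noise_sd=0.0, seed=7)
    sc.drift_slope_per_s = 0.0
    vm_raw, ca_raw, truth = make_movie_pair(sc)
    mask = segment_tissue_mask(vm_raw, 0.2)
    return normalize_pixelwise(vm_raw), normalize_pixelwise(ca_raw), mask, truth


@pytest.fixture(scope="session")
def plane_wave_stack():
    """A left-to-right plane wave: activation advances 0.7 ms per column
    (0.35 mm pitch at 0.5 mm/ms).  The upstroke is a 6 ms logistic so the
    4 ms sampling can resolve sub-frame activation shifts."""
    from scipy.special import expit

    n_rows, n_cols, n_frames = 8, 16, 120
    t = np.arange(n_frames) * 4.0
    data = np.zeros((n_frames, n_rows, n_cols))
    for c in range(n_cols):
        t0 = 40.0 + 0.7 * c
        v = expit((t - t0) / 6.0) * expit((t0 + 240.0 - t) / 15.0)
        data[:, :, c] = v[:, None]
    meta = AcquisitionMeta(4.0, 0.35, n_rows, n_cols, "vm", "up")
    return MovieStack(data, meta)
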