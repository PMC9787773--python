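import warnings

import numpy as np
import pytest

from acmems.msdata import Observation
from acmems.simulate import generate_golden

warnings.filterwarnings("ignore", message="Covariance of the parameters")


@pytest.fixture
def tiny_obs() -> Observation:
    """2x2 grid [[1,2],[3,4]] with unit-ish axes, used for hand-derived sums."""
    return Observation(
        counts=np.array([[1.0, 2.0], [3.0, 4.0]]),
        mz_axis=np.array([100.0, 100.08]),
        time_axis=np.array([10.0, 10.5]),
    )


def make_obs(counts, mz0=70.0, dmz=0.08, t0=0.0, dt=0.5, meta=None):
    counts = np.asarray(counts, dtype=float)
    n_mz, n_time = counts.shape
    return Observation(
        counts=counts,
        mz_axis=mz0 + dmz * np.arange(n_mz),
        time_axis=t0 + dt * np.arange(n_time),
        meta=meta or {},
    )


def gaussian_peak_grid(shape, row, col, height, sigma_mz_bins, sigma_t_bins,
                       background=0.0):
    """Noiseless grid with one separable 2D Gaussian peak."""
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    peak = height * np.exp(
        -0.5 * ((rows - row) / sigma_mz_bins) ** 2
        - 0.5 * ((cols - col) / sigma_t_bins) ** 2
    )
    return background + peak


@pytest.fixture(scope="session")
def mini_golden():
    """Small golden-style sample shared by detection-level tests."""
    return generate_golden(seed=7, n_peaks=12, grid_shape=(200, 600))
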