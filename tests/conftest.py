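import numpy as np
import pytest

from pasmap.synthetic import CohortSpec, cohort_mask, default_grid
from pasmap.volumes import GridGeometry, TimeSeriesVolume


@pytest.fixture
def small_grid() -> GridGeometry:
    """Tiny grid with hemispheres split cleanly at x = 0 (no midline voxels)."""
    return default_grid((6, 6, 6), 3.0)


@pytest.fixture
def sim_grid() -> GridGeometry:
    """Reduced simulation grid used by the heavier group-level studies."""
    return default_grid((12, 14, 12), 3.0)


@pytest.fixture
def small_cohort_spec(small_grid) -> CohortSpec:
    return CohortSpec(
        n_patients=3, n_controls=3, n_timepoints=80, grid=small_grid, seed=7
    )


@pytest.fixture
def small_mask(small_cohort_spec):
    return cohort_mask(small_cohort_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_volume(grid: GridGeometry, data: np.ndarray, tr: float = 2.0) -> TimeSeriesVolume:
    return TimeSeriesVolume(data=data, geometry=grid, tr_seconds=tr)


def exchange_symmetric_volume(grid, label, c=0.5, n_t=60, seed=0):
    """Volume whose sample correlation matrix is *exactly* equicorrelated
    (every pair r = c), hence invariant under the left/right exchange.

    Built from exactly orthonormal mean-zero vectors (QR), so the uniform
    correlation holds to machine precision, not just in expectation.  This
    is the symmetry that forces PAS = 0: with literally mirrored series the
    mirror twin would contribute r = 1 to the inter side only (the intra
    side excludes the seed itself), so PAS would be strictly positive.
    """
    rng = np.random.default_rng(seed)
    n_vox = int((label > 0).sum())
    if n_t < n_vox + 2:
        raise ValueError("need n_t >= n_voxels + 2 for exact orthonormal columns")
    m = rng.standard_normal((n_t, n_vox + 1))
    ones = np.ones((n_t, 1)) / np.sqrt(n_t)
    m -= ones @ (ones.T @ m)  # mean-zero columns
    q, _ = np.linalg.qr(m)
    shared, per_vox = q[:, 0], q[:, 1:]
    series = np.sqrt(c) * shared[None, :] + np.sqrt(1 - c) * per_vox.T
    data = np.zeros((*grid.shape, n_t))
    data[label > 0] = series
    return TimeSeriesVolume(data=data, geometry=grid)
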