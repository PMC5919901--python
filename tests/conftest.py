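import numpy as np
import pytest
from scipy import ndimage

from paleobrain.imaging_core import ScalarVolume, VoxelGrid
from paleobrain.synthetic_cohort import atlas_region_table, make_canonical_phantom


@pytest.fixture(scope="session")
def canonical():
    return make_canonical_phantom()


@pytest.fixture(scope="session")
def region_table():
    return atlas_region_table()


def smoothed_sphere(radius: float, shape=(48, 48, 48), fwhm: float = 2.0,
                    center=None) -> ScalarVolume:
    """Gaussian-smoothed sphere indicator (test phantom helper)."""
    grid = VoxelGrid(shape)
    idx = np.stack(np.meshgrid(*[np.arange(float(s)) for s in shape],
                               indexing="ij"), axis=-1)
    c = np.asarray(center) if center is not None else (np.array(shape) - 1) / 2.0
    r = np.linalg.norm(idx - c, axis=-1)
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    vals = ndimage.gaussian_filter((r <= radius).astype(float), sigma)
    return ScalarVolume(grid, vals)


def smooth_random_velocity(shape, amplitude, sigma=3.0, seed=0, taper=6):
    """Smooth random velocity lattice decaying toward the grid boundary.

    White noise is tapered first and smoothed afterwards, so the field stays
    smooth everywhere while being small near the edges (where clamping would
    otherwise corrupt flow integration)."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=tuple(shape) + (3,))
    w = np.ones(shape)
    for ax, s in enumerate(shape):
        ramp = np.clip(np.minimum(np.arange(s), np.arange(s)[::-1]) / taper, 0, 1)
        sh = [1, 1, 1]
        sh[ax] = -1
        w = w * ramp.reshape(sh)
    v = ndimage.gaussian_filter(noise * w[..., None], (sigma,) * 3 + (0.0,))
    v *= amplitude / max(np.abs(v).max(), 1e-12)
    return v
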