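import numpy as np
import pytest

from adenovol import GridSpec, MaskGrid, PhantomConfig, VolumeGrid, make_phantom


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(shape=(32, 32, 32), spacing=1.0)


@pytest.fixture(scope="session")
def small_phantom_cfg(small_grid) -> PhantomConfig:
    # Small tumors so they fit a 32 mm grid.
    return PhantomConfig(
        grid=small_grid, tumor_radii_range=(4.0, 6.0), center_jitter=2.0, seed=11
    )


@pytest.fixture(scope="session")
def study_pair(small_phantom_cfg):
    return make_phantom(small_phantom_cfg, "P000")


def random_mask(rng: np.random.Generator, shape=(16, 16, 16), p=0.2) -> np.ndarray:
    """A random blob-ish binary mask (thresholded smoothed noise)."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2)
    thr = np.quantile(field, 1 - p)
    return (field >= thr).astype(np.uint8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def ras_volume(data: np.ndarray, spacing=1.0, phase="preop") -> VolumeGrid:
    aff = np.diag([spacing] * 3 + [1.0])
    return VolumeGrid(data, aff, phase)


def mask_grid(data: np.ndarray, spacing=1.0) -> MaskGrid:
    aff = np.diag([spacing] * 3 + [1.0])
    return MaskGrid(data, aff)
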