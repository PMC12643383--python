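import dataclasses

import numpy as np
import pytest

from octaskin import OCTAVolume, PhantomSpec, generate_phantom
from octaskin.phantom import rasterize_trees, generate_vessel_trees


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A desk-scale phantom: 48 depth slices, 64x64 en face, two bands."""
    return PhantomSpec(shape=(48, 64, 64), boundary_index=16, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """(rendered volume, ground-truth mask) for the small spec."""
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def gt_mask(small_phantom):
    return small_phantom[1]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def make_step_volume(surface: np.ndarray, depth: int, bright: float = 1.0,
                     background: float = 0.0) -> OCTAVolume:
    """A volume that is `background` above the surface index and `bright`
    from the surface downwards (a clean tissue-entry interface)."""
    ny, nx = surface.shape
    z = np.arange(depth)[:, None, None]
    data = np.where(z >= surface[None, :, :], bright, background)
    return OCTAVolume(data=data.astype(np.float32))


@pytest.fixture(scope="session")
def straight_tube_mask():
    """A single straight radius-3 tube along x in a 32x32x64 volume."""
    shape = (32, 32, 64)
    zz, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    disc = (zz - 16) ** 2 + (yy - 16) ** 2 <= 3 ** 2
    data = np.zeros(shape, dtype=bool)
    data[disc, :] = True
    return data
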