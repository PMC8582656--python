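import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from thyradiomics.features import GrayLevelMap
from thyradiomics.synth import PhantomParams, generate_thyroid_phantom
from thyradiomics.volio import RoiMask, VoxelVolume


def make_glmap(levels: np.ndarray) -> GrayLevelMap:
    """Wrap an integer level array (0 = outside ROI) as a GrayLevelMap."""
    levels = np.asarray(levels, dtype=np.int64)
    mask = levels > 0
    return GrayLevelMap(
        levels=levels,
        mask=mask,
        n_levels=int(levels.max()),
        bin_width=1.0,
        spacing=(1.0, 1.0, 1.0),
    )


@pytest.fixture(scope="session")
def small_phantom():
    """A deterministic textured phantom at 1 mm isotropic spacing."""
    params = PhantomParams(seed=7)
    return generate_thyroid_phantom(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_glmap(rng, max_side=5, n_levels=4, p_mask=0.8) -> GrayLevelMap:
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    levels = rng.integers(1, n_levels + 1, size=shape)
    levels[rng.random(shape) > p_mask] = 0
    if not (levels > 0).any():
        levels[0, 0, 0] = 1
    return make_glmap(levels)
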