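import numpy as np
import pytest

from ardecon import VoxelGrid, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_grid(rng):
    """16-cubed random volume, pixel size 1 A."""
    return VoxelGrid(rng.standard_normal((16, 16, 16)), 1.0)


@pytest.fixture(scope="session")
def phantom32():
    return make_phantom(32, 1.0, n_blobs=12, seed=0)


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(64, 1.0, n_blobs=30, seed=0)
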