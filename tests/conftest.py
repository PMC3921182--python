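import numpy as np
import pytest

from soarsel.grids import Raster


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def split_raster():
    """20x20 grid (100 m cells) split left/right into classes 1 and 2."""
    values = np.ones((20, 20), dtype=int)
    values[:, 10:] = 2
    return Raster(values, (0.0, 0.0), 100.0)


@pytest.fixture()
def cluster_points(rng):
    """A single tight Gaussian cluster, dense relative to the 100 m grid."""
    return rng.normal([1000.0, 1000.0], 100.0, size=(800, 2))
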