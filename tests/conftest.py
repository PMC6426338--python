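import numpy as np
import pytest

from forestclim import GeoGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_grid(values, mask=None, origin_lon=-60.0, origin_lat=0.0, res=0.05):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return GeoGrid(values, mask, origin_lon, origin_lat, res)


@pytest.fixture
def grid_factory():
    return make_grid
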