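import numpy as np
import pytest

from wingpol.hexgrid import HexGrid
from wingpol.model.core import CoreParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    return HexGrid(4, 8)


@pytest.fixture(scope="session")
def default_grid():
    return HexGrid(6, 30)


@pytest.fixture(scope="session")
def fast_params():
    """Default rates; used with short horizons on small grids in unit tests."""
    return CoreParams()
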