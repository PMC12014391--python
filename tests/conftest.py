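import numpy as np
import pytest

from adhesiometry import chamber, synthetic
from adhesiometry.profiles import WeibullParams


@pytest.fixture(scope="session")
def geometry():
    return chamber.default_geometry()


@pytest.fixture(scope="session")
def flow(geometry):
    return synthetic.default_flow(geometry)


@pytest.fixture(scope="session")
def host():
    return synthetic.DEFAULT_HOST


@pytest.fixture(scope="session")
def cancer():
    return synthetic.DEFAULT_CANCER


@pytest.fixture(scope="session")
def bin_shears(geometry, flow):
    _, tau = chamber.bin_edges(geometry, flow)
    return tau


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
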