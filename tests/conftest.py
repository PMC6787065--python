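import numpy as np
import pytest

from nfixbox.circulation import make_circulation
from nfixbox.forcing import make_climatology, make_fe_deposition, make_n_deposition
from nfixbox.geometry import make_geometry
from nfixbox.params import ModelParams


@pytest.fixture(scope="session")
def geometry():
    return make_geometry()


@pytest.fixture(scope="session")
def mild_circulation():
    return make_circulation("mild")


@pytest.fixture(scope="session")
def mild_climatology(geometry):
    return make_climatology(geometry, "mild")


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)
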