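import numpy as np
import pytest
from hypothesis import settings

from astroca import AstroParams, Geometry, build_chain_model

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Printed parameter table."""
    return AstroParams()


@pytest.fixture(scope="session")
def cal_params():
    """Working (calibrated) parameter set used for simulations."""
    return AstroParams.calibrated()


@pytest.fixture(scope="session")
def control_geometry():
    return Geometry()


@pytest.fixture(scope="session")
def chain15(control_geometry):
    return build_chain_model(15, control_geometry)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
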