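import numpy as np
import pytest

from canopyflux.config import RunConfig
from canopyflux.solar import SiteGeometry
from canopyflux.stomatal import StomatalParams


@pytest.fixture(scope="session")
def site():
    """The high-altitude semi-arid maize site used throughout."""
    return SiteGeometry(latitude=37.87, longitude=102.85, altitude=1581.0)


@pytest.fixture(scope="session")
def default_params():
    return StomatalParams()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
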