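import numpy as np
import pytest

from panelflash.flow import calibrate_field
from panelflash.geometry import build_geometry
from panelflash.light import fit_attenuation

PRINTED_LIGHT_PAIRS = [(0.28, 5.0), (0.85, 2.0), (1.7, 1.0)]


@pytest.fixture(scope="session")
def geom():
    """Default baffled panel geometry."""
    return build_geometry()


@pytest.fixture(scope="session")
def geom_unbaffled():
    return build_geometry({"baffle_count": 0})


@pytest.fixture(scope="session")
def light_model():
    """Attenuation model fitted to all three printed calibration pairs."""
    return fit_attenuation(PRINTED_LIGHT_PAIRS)


@pytest.fixture(scope="session")
def field_baffled_002(geom):
    return calibrate_field(geom, 0.02, baffled=True)


@pytest.fixture(scope="session")
def field_unbaffled_002(geom_unbaffled):
    return calibrate_field(geom_unbaffled, 0.02, baffled=False)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
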