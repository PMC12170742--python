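import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from repskew import Grids, ModelParams

settings.register_profile(
    "repskew",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repskew")

#: the three quality-productivity columns of the study design, with the
#: minimal helping effect tied to the QPC by m = 0.6 - a/2
COLUMNS = ((-0.5, 0.85), (0.5, 0.35), (1.5, -0.15))


@pytest.fixture(scope="session")
def baseline():
    """Baseline parameters: b = 1, r = 0.25, a = 0.5, m = 0.35."""
    return ModelParams()


@pytest.fixture(scope="session")
def grids():
    """Full default grids (201-point state grids, 1001-point share grid)."""
    return Grids.default()


@pytest.fixture(scope="session")
def small_grids():
    """Coarser grids for unit tests where full resolution is unnecessary."""
    return Grids.default(81, y_coarse=401)
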