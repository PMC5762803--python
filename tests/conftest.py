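import numpy as np
import pytest

from abiret.model import RockingCurve, WorkingPoints

#: half-maximum offset for sigma = 8.6: sigma * sqrt(2 ln 2)
HALF_SLOPE = 10.125726193633081


@pytest.fixture(scope="session")
def rc() -> RockingCurve:
    """Si(111)-like analyzer width at 17 keV."""
    return RockingCurve(sigma=8.6)


@pytest.fixture(scope="session")
def cardinal_points() -> WorkingPoints:
    """Low half slope, peak, high half slope."""
    return WorkingPoints((-HALF_SLOPE, 0.0, HALF_SLOPE))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
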