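import numpy as np
import pytest

from stereospeed import SpeedChangeInterval, ViewingGeometry


@pytest.fixture(scope="session")
def geom() -> ViewingGeometry:
    return ViewingGeometry()


@pytest.fixture(scope="session")
def fast_standard() -> SpeedChangeInterval:
    return SpeedChangeInterval(40.0, 40.0)


@pytest.fixture(scope="session")
def fast_max() -> SpeedChangeInterval:
    return SpeedChangeInterval(10.0, 70.0)


@pytest.fixture(scope="session")
def slow_standard() -> SpeedChangeInterval:
    return SpeedChangeInterval(20.0, 20.0)


@pytest.fixture(scope="session")
def slow_max() -> SpeedChangeInterval:
    return SpeedChangeInterval(5.0, 35.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024097)
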