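import numpy as np
import pytest

from tubepump.frames import OpticsConfig
from tubepump.scenarios import outflow_like, ventricle_like


@pytest.fixture(scope="session")
def optics():
    return OpticsConfig()


@pytest.fixture(scope="session")
def vent_scenario():
    return ventricle_like(drive_seed=1)


@pytest.fixture(scope="session")
def outflow_scenario():
    return outflow_like(drive_seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
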