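import numpy as np
import pytest

from denitkin import carbonate as carb
from denitkin.gas import BottleConfig


@pytest.fixture(scope="session")
def cfg() -> BottleConfig:
    return BottleConfig()


@pytest.fixture(scope="session")
def k30() -> carb.CarbonateConstants:
    return carb.equilibrium_constants(303.15)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
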