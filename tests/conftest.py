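import numpy as np
import pytest

from optotherm.mc_light import TissueOpticalProperties, propagate
from optotherm.protocol import FiberSource


@pytest.fixture(scope="session")
def red_props():
    return TissueOpticalProperties.brain(638)


@pytest.fixture(scope="session")
def fiber():
    return FiberSource()


@pytest.fixture(scope="session")
def fluence_small(fiber, red_props):
    """Moderate-size transport run in the lateral-fiber geometry, shared by
    tests that only need a representative fluence grid."""
    return propagate(80_000, fiber, red_props, seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
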