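import numpy as np
import pytest

from bloommap import DEFAULT_BOUNDARY, DEFAULT_CONSTANTS
from bloommap.synthetic import make_scene


@pytest.fixture(scope="session")
def boundary():
    return DEFAULT_BOUNDARY


@pytest.fixture(scope="session")
def unit_f_constants():
    return DEFAULT_CONSTANTS.with_unit_f()


@pytest.fixture(scope="session")
def coastal_scene():
    """A mixed coastal scene with ground truth, shared across read-only tests."""
    return make_scene(shape=(96, 96), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
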