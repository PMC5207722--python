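import numpy as np
import pytest

from sigbnet.params import make_default_params
from sigbnet.model import steady_state


@pytest.fixture(scope="session")
def default_params():
    return make_default_params()


@pytest.fixture(scope="session")
def kin(default_params):
    return default_params[0]


@pytest.fixture(scope="session")
def op(default_params):
    return default_params[1]


@pytest.fixture(scope="session")
def ss_unstressed(kin, op):
    return steady_state(kin, op, 0.0)


@pytest.fixture(scope="session")
def ss_stressed(kin, op):
    return steady_state(kin, op, 0.5)
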