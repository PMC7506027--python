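import numpy as np
import pytest
from hypothesis import settings

from einet import NetworkParams, Protocol

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Reference parameter set."""
    return NetworkParams()


@pytest.fixture(scope="session")
def small_params():
    """A miniature network for fast simulation tests."""
    return NetworkParams(N_e=80, N_i=20)


@pytest.fixture(scope="session")
def short_protocol():
    return Protocol(t_total=600.0, t_step=300.0, burn_in=100.0,
                    measure_window=250.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
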