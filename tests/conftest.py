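import numpy as np
import pytest

from dfc_cl.network import DynamicsConfig, init_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params(rng):
    """A small random tanh network: 3 -> 4 -> 3 -> 2."""
    return init_params([3, 4, 3, 2], rng)


@pytest.fixture
def quiet_dynamics():
    """Controller switched off: the dynamics relax to the feedforward pass."""
    return DynamicsConfig(k_p=0.0, k_i=0.0, alpha_leak=0.0, convergence_tol=1e-9)
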