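import numpy as np
import pytest

from pyrdyn import (POOLS_NCM3722, default_parameters, find_steady_state,
                    integrate, synth)


@pytest.fixture(scope="session")
def p_default():
    return default_parameters()


@pytest.fixture(scope="session")
def ext():
    return POOLS_NCM3722


@pytest.fixture(scope="session")
def steady_state(p_default, ext):
    xs = find_steady_state(p_default, ext)
    assert xs is not None
    return xs


@pytest.fixture(scope="session")
def oscillatory_trajectory(ext):
    """Limit-cycle trajectory of the packaged oscillation-capable set."""
    return integrate(synth.make_oscillatory_base(), ext, t_end=2.0e5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_states(rng, n, scale=3.0):
    """Random non-negative 9-component states spanning several decades."""
    mag = 10.0 ** rng.uniform(-4, np.log10(scale), size=(n, 9))
    mask = rng.random((n, 9)) < 0.1
    mag[mask] = 0.0
    return mag
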