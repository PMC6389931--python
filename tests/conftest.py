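import numpy as np
import pytest

from fgmosaic import ParameterSet, mosaic_system


@pytest.fixture(scope="session")
def defaults() -> ParameterSet:
    """Baseline constants: b=11, c=1, s=10, h=2, unit gains and exponents."""
    return ParameterSet()


@pytest.fixture(scope="session")
def mosaic():
    return mosaic_system()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def central_diff_jacobian(fun, y, h=1e-6):
    """Simple central-difference Jacobian used as the derivative oracle."""
    y = np.asarray(y, float)
    f0 = np.asarray(fun(y))
    J = np.zeros((f0.size, y.size))
    for j in range(y.size):
        e = np.zeros_like(y)
        e[j] = h
        J[:, j] = (np.asarray(fun(y + e)) - np.asarray(fun(y - e))) / (2 * h)
    return J
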