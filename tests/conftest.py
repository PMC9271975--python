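import numpy as np
import pytest

from tumoreq.fields import FormFunction, ImmuneParameters, RadialGrid


@pytest.fixture(scope="session")
def radial_grid():
    return RadialGrid(1.0, 100)


@pytest.fixture(scope="session")
def immune_params():
    """Lower-bound immune/environment parameters of the study setup."""
    return ImmuneParameters(chi=86.4, D=8.64e-5, gamma=2e-2, K=1e-2,
                            R_influx=1.74e-7)


@pytest.fixture(scope="session")
def immune_params_nodrift():
    """Same parameters with the chemotactic drift switched off.

    chi = 1e-300 underflows every drift velocity to exactly zero, making the
    stationary immune equation exactly linear in the tumor mass.
    """
    return ImmuneParameters(chi=1e-300, D=8.64e-5, gamma=2e-2, K=1e-2,
                            R_influx=1.74e-7)


@pytest.fixture(scope="session")
def delta_form():
    return FormFunction(2.0, 0.1)


@pytest.fixture(scope="session")
def sigma_form():
    return FormFunction(5e-17, 0.1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
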