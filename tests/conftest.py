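import numpy as np
import pytest

import exosim as ex
from exosim.engine import IntegratorOptions, integrate, scenario


@pytest.fixture(scope="session")
def p():
    return ex.default_parameters()


@pytest.fixture(scope="session")
def pc(p):
    return p.canonical()


@pytest.fixture(scope="session")
def neuron_rest(p):
    from exosim.neuron import resting_state

    return resting_state(p)


@pytest.fixture(scope="session")
def fig2_result(p):
    """The 500 ms, 20 uA/cm^2 pulse run, shared across tests."""
    return integrate(scenario("fig2_neuron_pulse", p, amplitude=20.0))


@pytest.fixture(scope="session")
def fig2_astro_result(p):
    return integrate(scenario("fig2_astrocyte", p))
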