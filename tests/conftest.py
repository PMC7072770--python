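"""Shared fixtures: the reference model and cached scenario runs."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from atmkin import (
    build_atm_network,
    default_parameters,
    reference_shuttling,
    run_scenario,
    stoichiometric_matrix,
)

settings.register_profile(
    "suite",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def network(params):
    return build_atm_network(params)


@pytest.fixture(scope="session")
def shuttling(network, params):
    return reference_shuttling(network, params)


@pytest.fixture(scope="session")
def stoich(network):
    return stoichiometric_matrix(network)


@pytest.fixture(scope="session")
def ir_outcome():
    """IR scenario (DR=1, T=1) on the default horizon, shared by many tests."""
    return run_scenario("ir")


@pytest.fixture(scope="session")
def blm_outcome():
    return run_scenario("blm")


@pytest.fixture(scope="session")
def oxidant_outcome():
    return run_scenario("oxidant")


@pytest.fixture(scope="session")
def sham_outcome():
    return run_scenario("sham")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
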