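import numpy as np
import pytest

from rcell import (
    default_host_params,
    fast_steady_state,
    no_burden_reference,
    steady_state,
)
from rcell.circuits import EMPTY_CIRCUIT, build_constitutive_gene


@pytest.fixture(scope="session")
def params():
    return default_host_params()


@pytest.fixture(scope="session")
def poi_gene():
    """Default constitutive gene-of-interest template."""
    return build_constitutive_gene().genes[0]


@pytest.fixture(scope="session")
def ref(params, poi_gene):
    """No-burden reference at the default nutrient quality (sigma = 0.5)."""
    return no_burden_reference(params, genes=[poi_gene])


@pytest.fixture(scope="session")
def host_ss(params):
    """Host-only steady state found by time integration (the contract path)."""
    return steady_state(params, EMPTY_CIRCUIT, horizon=200.0, tol=1e-9)


@pytest.fixture(scope="session")
def host_ss_fast(params):
    return fast_steady_state(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240304)
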