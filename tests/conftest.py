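import pytest

from molarisk import McmcConfig, SimulationParams, load_table1_fixture, simulate_cohort


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture
def fast_mcmc():
    """Reduced sampler budget for unit tests that only need rough posteriors."""
    return McmcConfig(n_chains=4, n_iterations=500, n_warmup=400, seed=123)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed fixed)."""
    return simulate_cohort(SimulationParams(seed=42))
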