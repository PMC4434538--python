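import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def locked():
    from airwaydx.classifier import locked_model

    return locked_model()


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted-structure training cohort (223 cancer / 76 benign,
    2000 genes, 11 clusters with six signal modules)."""
    from airwaydx.synthetic import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    from airwaydx.synthetic import null_config, simulate_cohort

    return simulate_cohort(null_config(seed=3, n_genes=10000))


@pytest.fixture(scope="session")
def locked_cohort(locked):
    """Cohort of 500 drawn from the locked classifier's own score."""
    from airwaydx.synthetic import simulate_from_locked

    return simulate_from_locked(locked, 500, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
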