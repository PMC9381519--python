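import numpy as np
import pytest

from slaml.synthetic import (
    DEFAULT_CUTOFFS,
    CohortConfig,
    default_archetypes,
    simulate_cohort,
    simulate_events,
)


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def cutoffs():
    return dict(DEFAULT_CUTOFFS)


@pytest.fixture(scope="session")
def small_cohort():
    """500-patient zero-jitter cohort shared across read-only tests."""
    return simulate_cohort(CohortConfig(n_patients=500, seed=42))


@pytest.fixture(scope="session")
def mpp_events(archetypes):
    return simulate_events(archetypes["MPP-L"], 10_000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
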