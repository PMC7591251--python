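import numpy as np
import pytest

from inthier import CohortSpec, RateModelParams, TracingSpec, gen_cohort, gen_connectivity
from inthier.synthetic_data import default_hierarchies


@pytest.fixture(scope="session")
def cohort_default():
    """One default synthetic cohort, shared across read-only tests."""
    int_matrix, cohort, truth = gen_cohort(CohortSpec(seed=7))
    return int_matrix, cohort, truth


@pytest.fixture(scope="session")
def hierarchies():
    return default_hierarchies()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for loops that refit many times."""
    spec = CohortSpec(n_patients=40, n_controls=30, n_parcels=23, seed=3)
    int_matrix, cohort, truth = gen_cohort(spec)
    return int_matrix, cohort, truth


@pytest.fixture(scope="session")
def tracing_network():
    """Synthetic 6-node tract-tracing network and its true hierarchy."""
    conn, h = gen_connectivity(TracingSpec(seed=0))
    return conn, h


@pytest.fixture(scope="session")
def rate_params():
    return RateModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
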