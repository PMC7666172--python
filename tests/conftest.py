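import numpy as np
import pytest

from stresssleep.synthetic import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cfg():
    return CohortConfig(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded cohort without the imaging arm, shared across tests."""
    from stresssleep.synthetic import generate_cohort

    return generate_cohort(CohortConfig(seed=42), include_imaging=False)
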