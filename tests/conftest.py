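import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject synthetic registry shared across tests."""
    from achondro.simulate import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_subjects=40, seed=11))


@pytest.fixture(scope="session")
def youth_cohort():
    """Cohort followed to 19 years, for curve/velocity pipelines."""
    from achondro.simulate import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_subjects=150, seed=5, age_last_years=19.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
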