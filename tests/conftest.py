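import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from utaref import GeneratorConfig, generate_cohort, make_fixture_bundle  # noqa: E402
from utaref.published import CRUDE_BETA, RESIDUAL_SD  # noqa: E402


@pytest.fixture(scope="session")
def fixture_bundle():
    return make_fixture_bundle(seed=7)


@pytest.fixture(scope="session")
def clean_cohort():
    """One realistic-size cohort drawn at the study conditions."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Cohort lying exactly on the generating cubic (zero residual SD)."""
    return generate_cohort(GeneratorConfig(n_subjects=300, residual_sd=0.0, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


CRUDE = np.asarray(CRUDE_BETA)
SD = RESIDUAL_SD
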