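import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctperf import CohortConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale geometry: fast to render, same statistical structure."""
    return CohortConfig(
        n_patients=4,
        matrix_size=48,
        n_slices=6,
        endo_radius_vox=8.0,
        epi_radius_vox=15.0,
        master_seed=123,
    )


@pytest.fixture(scope="session")
def noise_free_config():
    return CohortConfig(
        n_patients=4,
        matrix_size=48,
        n_slices=6,
        endo_radius_vox=8.0,
        epi_radius_vox=15.0,
        noise_sd=0.0,
        master_seed=123,
    )


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_config):
    return generate_cohort(noise_free_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
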