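import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy cohort with a planted negative fatigue effect."""
    from reactfc import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(
        grid_dims=(10, 10, 10),
        n_systems=3,
        n_subjects=16,
        n_timepoints=48,
        noise_sigma=0.5,
        effect_beta=-0.8,
        seed=7,
    )
    return generate_cohort(cfg)
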