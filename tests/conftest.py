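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
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_settings():
    """Short scenes for fast end-to-end tests: 1 s at 50 fps, 2 ms steps."""
    from kinetree import SimulationSettings

    return SimulationSettings(duration=1.0, sim_dt=0.002, frame_dt=0.02, tau=1.5)


@pytest.fixture(scope="session")
def small_cohort(small_settings):
    """Six synthetic 4-AFC participants with short scenes and 60 trials."""
    from kinetree import make_cohort

    datasets, specs = make_cohort(
        n_participants=6, seed=777, n_unique=30, settings=small_settings
    )
    return datasets, specs
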