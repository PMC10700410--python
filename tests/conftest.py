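import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stopdrive as sd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def config():
    return sd.TaskConfig()


@pytest.fixture
def fine_config():
    """Fine-step (600 Hz) variant used for oracle checks."""
    return sd.TaskConfig(sample_rate=600.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small fitted cohort shared across reliability/pipeline tests."""
    config = sd.TaskConfig()
    spec = sd.CohortSpec(n_subjects=24, trials_per_session=10, seed=7)
    cohort = sd.sample_cohort(spec)
    trajs = sd.generate_cohort_trajectories(cohort, config, spec)
    fits = sd.fit_trajectories(trajs, config)
    return {
        "spec": spec,
        "cohort": cohort,
        "trajs": trajs,
        "fits": fits,
        "fits_frame": sd.fits_to_frame(fits),
        "config": config,
    }
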