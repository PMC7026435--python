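import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    from bdstaging import StagingModel

    return StagingModel()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient baseline cohort with validators, fixed seed."""
    from bdstaging.cohort import attach_external_validators, default_config, generate_baseline

    cfg = default_config(300)
    rng = np.random.default_rng(2026)
    cohort = generate_baseline(cfg, seed=rng)
    return attach_external_validators(cohort, cfg, seed=rng)


@pytest.fixture(scope="session")
def longitudinal_cohort():
    """Baseline + follow-up + pairs for a 500-patient cohort, fixed seed."""
    from bdstaging.cohort import attach_external_validators, default_config, evolve_cohort, generate_baseline

    cfg = default_config(500)
    rng = np.random.default_rng(7)
    baseline = attach_external_validators(generate_baseline(cfg, seed=rng), cfg, seed=rng)
    followup, pairs = evolve_cohort(baseline, cfg, seed=rng)
    followup = attach_external_validators(followup, cfg, seed=rng)
    return baseline, followup, pairs
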