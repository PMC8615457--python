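import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wbam import (
    CohortConfig,
    MCMCConfig,
    ModelSpec,
    SyntheticGaitConfig,
    fit_model,
    generate_cohort,
    generate_synthetic_gait,
    pair_trials,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Reduced-size sampler settings for unit tests: still 4 chains so R^ is
#: meaningful, but short enough that a fit takes ~1 s.
FAST_MCMC = MCMCConfig(chains=4, iterations=600, warmup=300, walkers=8, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    dataset, truth = generate_cohort(CohortConfig(seed=7))
    return dataset, truth


@pytest.fixture(scope="session")
def paired_default(default_cohort):
    dataset, _ = default_cohort
    return pair_trials(dataset)


@pytest.fixture(scope="session")
def model1_fit(paired_default):
    return fit_model(ModelSpec(1), paired_default, config=FAST_MCMC)


@pytest.fixture(scope="session")
def gait_trial():
    config = SyntheticGaitConfig()
    trial, truth = generate_synthetic_gait(config)
    return config, trial, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
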