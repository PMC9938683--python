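import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chronoactivity import scenarios
from chronoactivity.simulate import (
    generate_epoch_cohort,
    generate_phenotype_cohort,
    generate_survival,
)
from chronoactivity.survival import add_modifier_columns

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=30,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def null_cohort():
    """Global-null survival cohort (no planted effects), n = 20,000."""
    config = scenarios.null_config(n=20_000, seed=101)
    cohort, _ = generate_phenotype_cohort(config)
    return generate_survival(cohort, config)


@pytest.fixture(scope="session")
def cvd_recovery_cohort():
    """Cohort with the published CVD model-3 hazard ratios planted."""
    config = scenarios.recovery_config("cvd", n=30_000, seed=21)
    cohort, _ = generate_phenotype_cohort(config)
    return add_modifier_columns(generate_survival(cohort, config))


@pytest.fixture(scope="session")
def epoch_cohort():
    """Small epoch-level cohort with 5% nocturnal outliers planted."""
    config = scenarios.epoch_cohort_config(
        n=40, seed=11, concentration=0.7, nocturnal_outlier_rate=0.05
    )
    series, truth = generate_epoch_cohort(config, 40)
    return series, truth


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
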