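import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bonescatter as bs

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale default cohort (54+54 samples, 19+54 patients), seed 1."""
    cfg = bs.default_config(seed=1)
    cohort, table = bs.simulate_cohort(cfg)
    return cfg, cohort, table


@pytest.fixture(scope="session")
def study_matrix(study_cohort):
    """Preprocessed cohort matrix of the seed-1 study cohort."""
    _cfg, cohort, table = study_cohort
    return bs.preprocess_cohort(cohort, table)


@pytest.fixture(scope="session")
def study_loso(study_matrix):
    """Leave-one-sample-out CV of the seed-1 study cohort."""
    return bs.cross_validate(study_matrix, mode="sample")


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny fast cohort for plumbing tests: 8+8 samples on a coarse grid."""
    cfg = bs.default_config(
        seed=5,
        grid=(10.0, 80.0, 0.25),
        design=bs.CohortDesign.balanced(8, 2),
    )
    cohort, table = bs.simulate_cohort(cfg)
    return cfg, cohort, table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
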