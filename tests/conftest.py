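import numpy as np
import pytest

from gaitbalance.cohort import CohortParams, generate_cohort_frame
from gaitbalance.pipeline import make_folds


@pytest.fixture(scope="session")
def study_cohort():
    """56-subject cohort at the default calibration, seed 1."""
    return generate_cohort_frame(CohortParams(n_subjects=56, seed=1))


@pytest.fixture(scope="session")
def study_folds():
    return make_folds(56, k=4, test_size=14, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
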