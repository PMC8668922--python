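import numpy as np
import pytest

from ergpred import CohortConfig, generate_cohort
from ergpred.analysis import feature_table_from_truth


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition synthetic cohort (55 individuals), shared across tests."""
    return generate_cohort(CohortConfig(seed=123))


@pytest.fixture(scope="session")
def small_cohort_table(small_cohort):
    return feature_table_from_truth(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
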