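import numpy as np
import pytest

from diabsub.cluster import standardize
from diabsub.synth import simulate_table1_cohort

CLASSIFIERS = ("onset_age", "bmi", "hba1c", "homa2b", "homa2ir")
LOG_COLUMNS = ("homa2b", "homa2ir")
GROUPS = ["MOD", "SIRD-RII", "MARD-II"]


@pytest.fixture(scope="session")
def table1_cohort():
    """One calibrated 687-row synthetic cohort, shared across tests."""
    return simulate_table1_cohort(seed=11)


@pytest.fixture(scope="session")
def standardized_cohort(table1_cohort):
    Z, params = standardize(
        table1_cohort, columns=CLASSIFIERS, log_columns=LOG_COLUMNS
    )
    return Z, params


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
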