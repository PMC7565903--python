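import numpy as np
import pytest

from ipmn_balance import CohortConfig, generate_cohort
from ipmn_balance.datasets import dp_worksheet, pd_worksheet


@pytest.fixture
def toy4():
    """Four patients: benign at mp 10% and 30%, malignant at 20% and 40%."""
    labels = np.array([0, 0, 1, 1], dtype=bool)
    mp = np.array([0.10, 0.30, 0.20, 0.40])
    return labels, mp


@pytest.fixture(scope="session")
def pd_table():
    return pd_worksheet()


@pytest.fixture(scope="session")
def dp_table():
    return dp_worksheet()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_pd=120, n_dp=80, seed=7))


def random_cohort(rng, n=None):
    """Labels and scores with a signal, for property tests."""
    n = n or int(rng.integers(10, 200))
    labels = rng.random(n) < rng.uniform(0.1, 0.6)
    if labels.all() or not labels.any():
        labels[0] = True
        labels[-1] = False
    mp = np.clip(rng.beta(2, 5, n) + 0.2 * labels, 0.0, 1.0)
    return labels, mp
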