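import numpy as np
import pytest
from hypothesis import settings

import mews_eval as me

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_table():
    return me.load_reference_table()


@pytest.fixture(scope="session")
def ref_counts():
    return me.reference_counts()


@pytest.fixture(scope="session")
def ref_cohort():
    return me.reference_cohort()


@pytest.fixture(scope="session")
def ref_fit(ref_cohort):
    return me.fit_logistic(ref_cohort)


@pytest.fixture()
def toy_cohort():
    """4 records spanning both classes and several scores."""
    return me.Cohort.from_arrays([0, 2, 3, 5], [0, 1, 0, 1])


def random_cohort(rng: np.random.Generator, n: int, s_max: int = 8) -> me.Cohort:
    """A random cohort guaranteed to contain both outcome classes and at
    least two distinct scores."""
    while True:
        scores = rng.integers(0, s_max + 1, size=n)
        outcomes = rng.integers(0, 2, size=n)
        if 0 < outcomes.sum() < n and len(np.unique(scores)) >= 2:
            return me.Cohort.from_arrays(scores, outcomes)
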