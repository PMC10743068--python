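import numpy as np
import pytest

from strokeprog.synthetic import CohortSpec, PhantomSpec, gen_ncct_phantoms, gen_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def ncct_subjects():
    """A small, deterministic phantom cohort shared across tests."""
    return gen_ncct_phantoms(PhantomSpec(n_subjects=40, shape=(23, 28, 23), seed=7))


@pytest.fixture(scope="session")
def cohort_table():
    cohort, truth = gen_cohort(CohortSpec(n=413, seed=3))
    return cohort, truth
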