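import numpy as np
import pandas as pd
import pytest

from gmdrkit.cohort import Cohort


def make_random_cohort(rng, n=60, m=3, maf=None):
    """Small random binary cohort with no structure (for oracle tests)."""
    mafs = maf or rng.uniform(0.1, 0.5, m)
    G = np.column_stack(
        [rng.binomial(1, q, n) + rng.binomial(1, q, n) for q in np.atleast_1d(mafs)]
    )
    y = rng.integers(0, 2, n)
    while y.min() == y.max():
        y = rng.integers(0, 2, n)
    cov = pd.DataFrame({"age": rng.normal(55, 10, n), "sex": rng.integers(0, 2, n).astype(float)})
    return Cohort([f"S{i}" for i in range(n)], G, y.astype(float), cov)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def study_cohort_seed1():
    from gmdrkit.simulate import study_cohort

    return study_cohort(seed=1)
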