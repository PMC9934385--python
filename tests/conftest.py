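import numpy as np
import pytest

from lqsso import standardize


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_instance(rng, n, p, sparsity=0.5, sigma=0.5):
    """A small random regression instance with standardized data."""
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p) * (rng.random(p) < sparsity)
    y = X @ beta + sigma * rng.standard_normal(n)
    return standardize(X, y), beta


@pytest.fixture
def small_data(rng):
    data, _ = random_instance(rng, 30, 6)
    return data
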