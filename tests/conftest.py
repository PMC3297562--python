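import numpy as np
import pytest

import ssll


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def iset33():
    return ssll.build_multi_indices(3, 3)


@pytest.fixture(scope="session")
def iset22():
    return ssll.build_multi_indices(2, 2)


def random_theta(rng, index_set, scale=2.0):
    return ssll.LogLinearParams(
        index_set, rng.uniform(-scale, scale, size=index_set.dim)
    )
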