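import numpy as np
import pytest

from lognecg.bounds import load_prototype, load_table_bounds
from lognecg.synth import random_inbox_params


@pytest.fixture(scope="session")
def bounds():
    return load_table_bounds()


@pytest.fixture(scope="session")
def prototype():
    return load_prototype()


@pytest.fixture(scope="session")
def proto_vec(prototype):
    return prototype.params.to_vector()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_inbox_vectors(bounds, n, seed):
    rng = np.random.default_rng(seed)
    return np.stack([random_inbox_params(rng, bounds) for _ in range(n)])


@pytest.fixture(scope="session")
def inbox_vectors(bounds):
    """A reusable batch of order-valid in-box parameter vectors."""
    return make_inbox_vectors(bounds, 50, seed=777)
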