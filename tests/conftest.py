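import numpy as np
import pytest

from sgmnet.network import BinaryNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_binary_network(n: int, p: float, rng: np.random.Generator) -> BinaryNetwork:
    """Erdős–Rényi helper used across graph-metric tests."""
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return BinaryNetwork(a | a.T)
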