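import numpy as np
import pytest

from r3d.contact import ContactMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def symmetric_random(n: int, rng: np.random.Generator, low: float = 0.5, high: float = 5.0):
    """Dense positive symmetric matrix (no zero marginals)."""
    a = rng.uniform(low, high, size=(n, n))
    return (a + a.T) / 2


@pytest.fixture
def random_matrix(rng) -> ContactMatrix:
    counts = symmetric_random(20, rng)
    return ContactMatrix(chrom="chrT", resolution=200_000, counts=counts)
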