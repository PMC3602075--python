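import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_instance(rng):
    """A well-conditioned random (P, Q, G) triple, M=30, N=12, K=3."""
    M, N, K = 30, 12, 3
    P = rng.random((M, K))
    Q = rng.dirichlet(np.ones(K), size=N).T
    G = rng.binomial(2, P @ Q).astype(np.int8)
    return P, Q, G
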