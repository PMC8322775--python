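import numpy as np
import pytest

from wgrmf.simulate import generate_scenario


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact planted-structure scenario shared across read-only tests."""
    return generate_scenario(
        n=20, m=12, rank_true=3, density=0.2, noise=0.0, seed=7,
        lncrna_seq_length=80, protein_seq_length=50, n_samples=10,
    )


def random_symmetric_similarity(rng, n):
    """Nonnegative symmetric similarity with zero diagonal."""
    S = rng.random((n, n))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 0.0)
    return S
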