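import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_gaussian_dataset(seed, n_features=2, n_samples=40, separation=2.0):
    """Two-class Gaussian blobs, balanced up to rounding."""
    rng = np.random.default_rng(seed)
    n_pos = n_samples // 2
    n_neg = n_samples - n_pos
    X = np.vstack(
        [
            rng.normal(-separation / 2, 1.0, size=(n_neg, n_features)),
            rng.normal(+separation / 2, 1.0, size=(n_pos, n_features)),
        ]
    )
    y = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    perm = rng.permutation(n_samples)
    return X[perm], y[perm]


@pytest.fixture
def gaussian_dataset():
    return make_gaussian_dataset(seed=0)
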