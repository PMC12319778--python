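import numpy as np
import pytest

from plsperm import TwoBlockDataset


@pytest.fixture
def toy_dataset() -> TwoBlockDataset:
    """Small fixed dataset: 12 observations, 5 X features, 3 Y features."""
    rng = np.random.default_rng(42)
    return TwoBlockDataset(
        rng.standard_normal((12, 5)), rng.standard_normal((12, 3))
    )


@pytest.fixture
def null_dataset() -> TwoBlockDataset:
    """iid-normal dataset with no cross-block structure (n=60, 90 x 10)."""
    rng = np.random.default_rng(7)
    return TwoBlockDataset(
        rng.standard_normal((60, 90)), rng.standard_normal((60, 10))
    )


def make_rank1_dataset(n=200, p=8, q=4, strength=0.9, seed=0, q_noise=0.5):
    """Dataset with a single shared latent score driving both blocks."""
    rng = np.random.default_rng(seed)
    s = rng.standard_normal(n)
    wx = rng.standard_normal(p)
    wy = rng.standard_normal(q)
    X = np.outer(s, wx) * strength + rng.standard_normal((n, p)) * (1 - strength)
    Y = np.outer(s, wy) * strength + rng.standard_normal((n, q)) * q_noise
    return TwoBlockDataset(X, Y)
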