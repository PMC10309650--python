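import numpy as np
import pytest

from engdd.features import PairDataset
from engdd.synthetic_data import SyntheticSpec, generate


def make_dataset(X: np.ndarray, y: np.ndarray) -> PairDataset:
    """Wrap a plain (X, y) problem as a PairDataset with dummy IDs."""
    X = np.asarray(X, dtype=float)
    half = X.shape[1] // 2
    pairs = [(f"d{i:05d}", f"t{i:05d}") for i in range(len(X))]
    return PairDataset(pairs, X, np.asarray(y, dtype=int),
                       d_drug=half, d_target=X.shape[1] - half)


def xor_blobs(n: int = 400, seed: int = 0) -> PairDataset:
    """Four Gaussian blobs in XOR layout — not linearly separable."""
    rng = np.random.default_rng(seed)
    centers = np.array([[-2, -2], [2, 2], [-2, 2], [2, -2]], dtype=float)
    labels = np.array([1, 1, 0, 0])
    idx = rng.integers(0, 4, size=n)
    X = centers[idx] + 0.5 * rng.standard_normal((n, 2))
    return make_dataset(X, labels[idx])


def separable_blobs(n: int = 200, seed: int = 0) -> PairDataset:
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = np.where(y[:, None] == 1, 2.0, -2.0) \
        + 0.6 * rng.standard_normal((n, 2))
    return make_dataset(X, y)


@pytest.fixture(scope="session")
def tiny_world():
    """Small planted world: 40 drugs x 12 targets, cheap feature dims."""
    spec = SyntheticSpec(n_drugs=40, n_targets=12, latent_rank=2,
                         p_drug=30, p_target=40, seed=11)
    return generate(spec)


@pytest.fixture(scope="session")
def default_world():
    """The default study-scale world (300 drugs x 30 targets)."""
    return generate(SyntheticSpec())
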