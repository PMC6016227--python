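from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from emobh.features import FeatureTable, extract_features

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from emobh.synthetic import generate_dataset


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table() -> FeatureTable:
    """Feature table from a small synthetic dataset (5 sessions/class),
    shared across tests that only need realistic features."""
    sessions = generate_dataset(5, base_seed=0)
    return extract_features(sessions)


@pytest.fixture(scope="session")
def blobs() -> tuple[np.ndarray, np.ndarray]:
    """Four widely separated Gaussian blobs in 8 dimensions."""
    rng = np.random.default_rng(7)
    centers = np.zeros((4, 8))
    for c in range(4):
        centers[c, 2 * c] = 20.0
        centers[c, 2 * c + 1] = -20.0
    X = np.vstack([centers[c] + rng.normal(0, 0.5, size=(25, 8)) for c in range(4)])
    y = np.repeat([1, 2, 3, 4], 25)
    return X, y
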