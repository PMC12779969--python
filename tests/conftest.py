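import numpy as np
import pytest

from even.classify import default_model, train_lda
from even.simulate import (
    NoiseSpec,
    SimulationSpec,
    build_training_set,
    simulate_levels,
    synth_phantom,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blob_phantom():
    """A clean structured composite: 8x8 grid of 64px tiles."""
    return synth_phantom(64, (8, 8), content="blobs", seed=7)


@pytest.fixture(scope="session")
def level_series(blob_phantom):
    """The 5-level degradation series of the shared phantom."""
    sim = SimulationSpec(noise=NoiseSpec(seed=7))
    return simulate_levels(blob_phantom, sim)


@pytest.fixture(scope="session")
def training_set():
    """The 40+40 synthetic training set (features, labels, groups)."""
    return build_training_set(40, 40, seed=11)


@pytest.fixture(scope="session")
def trained_model(training_set):
    X, y, _ = training_set
    return train_lda(X, y)


@pytest.fixture(scope="session")
def packaged_model():
    return default_model()
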