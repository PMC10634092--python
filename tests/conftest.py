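import numpy as np
import pytest

from fermsensor.simulate import SimulatorConfig, build_dataset


@pytest.fixture(scope="session")
def four_blobs():
    """Four well-separated spherical Gaussian blobs (50 points each)."""
    rng = np.random.default_rng(0)
    centers = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0], [8.0, 8.0]])
    data = np.vstack([c + rng.normal(0, 0.6, size=(50, 2)) for c in centers])
    labels = np.repeat(np.arange(4), 50)
    return data, labels


@pytest.fixture(scope="session")
def small_dataset():
    """3-batch interpolated dataset (fast; for structural tests)."""
    cfg = SimulatorConfig(seed=7)
    return build_dataset(3, cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-jitter 10-batch dataset (measurement noise kept) for
    correlation-structure checks."""
    cfg = SimulatorConfig(seed=3, batch_jitter_sd=0.0)
    return build_dataset(10, cfg)
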