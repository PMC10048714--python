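import numpy as np
import pytest

from pearfuse.acquisition import split_indices
from pearfuse.synthetic_data import SyntheticConfig, generate_paired_dataset


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """Small but non-trivial study: 24 samples, default effects/noise."""
    return SyntheticConfig(n_per_class=12, image_size_px=64, seed=42)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_paired_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    tr, va = split_indices(tiny_dataset.labels, 0.7, seed=0)
    return tiny_dataset.subset(tr), tiny_dataset.subset(va)


@pytest.fixture(scope="session")
def separable_spectra():
    """Linearly separable 2-band toy spectra, 10 samples per class."""
    rng = np.random.default_rng(0)
    X0 = np.array([0.1, 0.9]) + 0.01 * rng.standard_normal((10, 2))
    X1 = np.array([0.9, 0.1]) + 0.01 * rng.standard_normal((10, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * 10 + [1] * 10)
    return X, y
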