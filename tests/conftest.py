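import numpy as np
import pytest

from seedvigor.models import CNNSpec, VigorCNN
from seedvigor.preprocess import split_dataset
from seedvigor.synthetic import (default_styles, make_domain_dataset,
                                 make_wavelength_grid)

# small, fast architecture used wherever the test only needs "a trained CNN"
FAST_SPEC = CNNSpec(conv_channels=(16, 32), learning_rate=0.005)


@pytest.fixture(scope="session")
def grid():
    return make_wavelength_grid()


@pytest.fixture(scope="session")
def styles():
    return default_styles()


@pytest.fixture(scope="session")
def small_dataset(grid, styles):
    """A small labelled single-variety dataset plus its 4:1:1 split."""
    data = make_domain_dataset(styles["yongyou12"], 60,
                               np.random.default_rng(11), grid=grid)
    split = split_dataset(data, np.random.default_rng(12), seed=12)
    return data, split


@pytest.fixture(scope="session")
def trained_fast(small_dataset):
    """One quickly trained CNN shared by tests that need a fitted model."""
    data, split = small_dataset
    X, y = data.spectra, data.labels
    return VigorCNN(FAST_SPEC, epochs=25).fit(
        X[split.train], y[split.train], X[split.val], y[split.val], seed=3,
        domain="yongyou12")


def separable_blobs(n_per_class=30, n_bands=181, seed=0):
    """Trivially separable 3-class spectra: disjoint plateaus per class."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cls in range(3):
        base = 0.2 + 0.25 * cls
        X.append(base + 0.01 * rng.standard_normal((n_per_class, n_bands)))
        y.extend([cls] * n_per_class)
    return np.vstack(X), np.asarray(y)
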