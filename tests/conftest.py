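import numpy as np
import pytest

from imbforest.datasets import (LabeledDataset, make_circle_data,
                                make_informative_gaussian)


@pytest.fixture
def circle_ds():
    """Small 2-D imbalanced dataset with two minority clumps."""
    return make_circle_data(113, 23, 0, seed=11)


@pytest.fixture
def circle_noisy_ds():
    """Circle data with 3 scattered minority noise points."""
    return make_circle_data(113, 23, 3, seed=11)


@pytest.fixture
def gaussian_ds():
    """3 informative + 7 noise features, effect size 2, 150 per class."""
    return make_informative_gaussian((150, 150), 3, 7, 2.0, seed=11)


@pytest.fixture
def tiny_imbalanced_ds():
    """Separable 40/10 two-feature dataset for fast sampler checks."""
    rng = np.random.RandomState(0)
    X = np.vstack([
        rng.normal(0.0, 0.4, size=(40, 2)),
        rng.normal(3.0, 0.3, size=(10, 2)),
    ])
    y = np.array([0] * 40 + [1] * 10)
    return LabeledDataset(X, y, positive_label=1)
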