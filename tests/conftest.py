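import numpy as np
import pytest

from mwrds import ExpressionMatrix, LabelVector, SimConfig, simulate_dataset


@pytest.fixture
def toy_matrix():
    """Minority {1,2,3}, majority {7,8,9,10,11} on feature 1; feature 2 constant.

    Hand-computable statistics for feature 1: class medians 2 and 9,
    pooled median 7.5, MADs 2/3 and 1.2, variances 1 and 2.5.
    """
    values = np.array(
        [[1.0, 4.0], [2.0, 4.0], [3.0, 4.0],
         [7.0, 4.0], [8.0, 4.0], [9.0, 4.0], [10.0, 4.0], [11.0, 4.0]]
    )
    X = ExpressionMatrix(values, feature_ids=("f1", "f2"))
    labels = LabelVector(np.array(["m", "m", "m", "M", "M", "M", "M", "M"]),
                         positive_label="m")
    return X, labels


@pytest.fixture
def small_signal_dataset():
    """100 samples, 9:1, 20 features of which the first 3 carry a big shift."""
    return simulate_dataset(
        SimConfig(n_samples=100, n_features=20, n_informative=3,
                  effect_size=3.0, seed=42)
    )


def random_dataset(seed, n_samples=None, n_features=None):
    """Small random imbalanced dataset for property tests."""
    rng = np.random.default_rng(seed)
    n = n_samples or int(rng.integers(8, 13))
    p = n_features or int(rng.integers(1, 7))
    n_min = int(rng.integers(2, n // 2 + 1))
    values = rng.normal(size=(n, p)) * rng.uniform(0.5, 3.0, size=p)
    labels = np.array(["m"] * n_min + ["M"] * (n - n_min))
    return (
        ExpressionMatrix(values),
        LabelVector(labels, positive_label="m"),
    )
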