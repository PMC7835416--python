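import numpy as np
import pytest

from nirkpls import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition synthetic dataset, scaled to 60 samples."""
    return generate_dataset(SyntheticConfig(n_samples=60), seed=7)


@pytest.fixture(scope="session")
def nonlinear_xy():
    """30-sample nonlinear regression problem for fit/predict tests."""
    rng = np.random.default_rng(99)
    X = rng.normal(size=(30, 5))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + 0.1 * rng.normal(size=30)
    return X, y
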