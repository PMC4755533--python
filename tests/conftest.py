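import numpy as np
import pytest

from transportc import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240916)


@pytest.fixture
def toy_univariable(rng):
    """n=200 univariable cohort with a real effect (slope ~1.5)."""
    x = rng.normal(0.0, 1.0, 200)
    y = (rng.random(200) < 1.0 / (1.0 + np.exp(-1.5 * x))).astype(float)
    return Dataset(y, x[:, None], ["x"], sample_label="development")


@pytest.fixture
def toy_bivariable(rng):
    """n=300 cohort with one informative and one weak predictor."""
    X = rng.normal(0.0, 1.0, (300, 2))
    lp = 1.2 * X[:, 0] + 0.4 * X[:, 1] - 0.3
    y = (rng.random(300) < 1.0 / (1.0 + np.exp(-lp))).astype(float)
    return Dataset(y, X, ["x1", "x2"])
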