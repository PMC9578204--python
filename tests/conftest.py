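import numpy as np
import pytest

from mccv.synthetic_data import FeatureSpec, FeatureTable, GeneratorConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """A 120-row default-design table, enough for 10-fold CV."""
    return generate(GeneratorConfig(n_samples=120, seed=42))


@pytest.fixture
def separable_table():
    """1-D perfectly separable toy data: x < 0 -> class 0, x >= 0 -> class 1."""
    rng = np.random.default_rng(7)
    x = np.concatenate([rng.uniform(-3, -0.5, 40), rng.uniform(0.5, 3, 40)])
    y = (x >= 0).astype(int)
    order = rng.permutation(80)
    return FeatureTable(
        x[order].reshape(-1, 1), y[order], (FeatureSpec("normal", sigma=1.0),)
    )
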