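import numpy as np
import pytest

from tracebench import LabeledMatrix, ModelConfig, SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def small_synthetic():
    """Well-separated 4-class fixture small enough for fast network training."""
    spec = SyntheticSpec(
        class_count=4, feature_count=30, exemplars_per_class=30,
        prototype_scale=3.0, irrelevant_rank=5, irrelevant_scale=1.0,
        noise_sd=0.5, seed=1,
    )
    return generate_synthetic(spec)


@pytest.fixture(scope="session")
def tiny_two_class():
    """20 trials, 2 features, 2 linearly separable classes with a known margin."""
    rng = np.random.default_rng(42)
    X0 = rng.normal(loc=(-2.0, 0.0), scale=0.3, size=(10, 2))
    X1 = rng.normal(loc=(+2.0, 0.0), scale=0.3, size=(10, 2))
    X = np.vstack([X0, X1])
    labels = np.repeat([0, 1], 10)
    return LabeledMatrix(X, labels, 2)


def fast_config(family: str, n: int, d: int = 2, k: int = 4, **kwargs) -> ModelConfig:
    defaults = dict(epochs=15, batch_size=32, seed=7, class_count=k)
    defaults.update(kwargs)
    return ModelConfig(family=family, input_dim=n, bottleneck_dim=d, **defaults)
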