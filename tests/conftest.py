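import numpy as np
import pytest

from quanvnet import ClassifierConfig, SyntheticImageSpec, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The package's default study conditions: 150 16x16 images, 3 classes."""
    return generate_dataset(SyntheticImageSpec(seed=0))


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small fast dataset for training-loop plumbing tests (8x8 images)."""
    spec = SyntheticImageSpec(image_size=8, n_per_class=6, seed=1)
    return generate_dataset(spec)


@pytest.fixture
def fast_config():
    """Short training config for plumbing tests (not the study conditions)."""
    return ClassifierConfig(epochs=2, batch_size=8, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
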