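import numpy as np
import pytest

from ihcscore.classifier import train_classifier
from ihcscore.synthetic.images import StainParams, generate_core_image


@pytest.fixture(scope="session")
def default_params():
    return StainParams()


@pytest.fixture(scope="session")
def small_core(default_params):
    """One deterministic 128x128 core with ground truth."""
    return generate_core_image(default_params, 128, 128, seed=7)


@pytest.fixture(scope="session")
def training_cores(default_params):
    return [generate_core_image(default_params, 128, 128, seed=s) for s in range(3)]


@pytest.fixture(scope="session")
def trained_model(training_cores):
    images = [img for img, _ in training_cores]
    truths = [gt for _, gt in training_cores]
    return train_classifier(images, truths, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
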