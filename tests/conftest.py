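import numpy as np
import pytest

from pdyolo import nn
from pdyolo.config import ModelConfig


@pytest.fixture(autouse=True)
def _seed_weight_init():
    """Every test starts from the same weight-init stream."""
    nn.seed_init(0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Nano-scale model with few classes; cheapest full build."""
    return ModelConfig(num_classes=3, input_size=(64, 64))


@pytest.fixture
def canonical_config():
    """The shipped 12-class configuration."""
    return ModelConfig()
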