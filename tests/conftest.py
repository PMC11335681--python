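import numpy as np
import pytest

from pancseg.cascade import CascadeConfig
from pancseg.phantom import PhantomConfig, generate_slice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom_config():
    return PhantomConfig(image_size=64, seed=7)


@pytest.fixture
def phantom_slice(phantom_config):
    return generate_slice(phantom_config, np.random.default_rng(7))


@pytest.fixture
def slim_cascade_config():
    """Small cascade for fast training-behaviour tests."""
    return CascadeConfig(
        image_size=32, stage2_size=32, base_channels=4, reduce_channels=8, seed=3
    )
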