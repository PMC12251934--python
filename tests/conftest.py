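import numpy as np
import pytest

from vimsa import ModelConfig, ViMSA
from vimsa.synthetic import easy_config


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


TINY = dict(image_height=32, image_width=32, patch_size=8, embed_dim=12,
            n_layers=1, n_heads=2, state_size=4)


@pytest.fixture
def tiny_model():
    """A minimal but fully assembled model for structural/gradient tests."""
    return ViMSA(ModelConfig(**TINY, seed=0))


@pytest.fixture
def tiny_images(rng):
    return rng.uniform(0, 255, size=(3, 32, 32))


@pytest.fixture
def clean_config():
    """Nuisance-free generator configuration at a small frame."""
    return easy_config(64, 48, seed=0)
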