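import numpy as np
import pytest

from hipposeg.model import ModelConfig
from hipposeg.phantom import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def micro_cfg():
    """A very small network config for fast unit tests (16^3 inputs)."""
    return ModelConfig(in_channels=2, base_channels=2, token_dim=8, n_heads=2,
                       cbam_reduction=2)


@pytest.fixture
def phantom_cfg():
    return PhantomConfig(grid_shape=(40, 40, 40), organ_axes=(13.0, 10.0, 8.0),
                         n_distractors=2, distractor_size_range=(30, 80),
                         noise_sd=0.02, bias_amplitude=0.1, seed=7)


@pytest.fixture
def clean_phantom_cfg():
    """Noise-free, bias-free, distractor-free phantom (exact intensities)."""
    return PhantomConfig(grid_shape=(40, 40, 40), organ_axes=(13.0, 10.0, 8.0),
                         n_distractors=0, noise_sd=0.0, bias_amplitude=0.0,
                         seed=3)
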