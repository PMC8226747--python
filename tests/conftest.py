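import numpy as np
import pytest
from hypothesis import settings

from nucseg.stain import NormalizationConfig

# property tests must replay identically everywhere
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from nucseg.synthetic import render_he, sample_layout, sample_style


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def he_tile():
    """One seeded synthetic H&E tile with its instance mask and style."""
    style = sample_style(np.random.default_rng(7))
    layout, mask = sample_layout((192, 192), 30, seed=8)
    image = render_he(mask, style, seed=9)
    return image, mask, style


@pytest.fixture()
def default_config():
    return NormalizationConfig()
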