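import numpy as np
import pytest

from panoquant import GreyImage
from panoquant.synthetic_data import MarkerConfig, SectionParams, generate_section


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_pair(rng):
    """Two random 64x64 grey images for per-pixel oracle checks."""
    a = GreyImage(rng.integers(0, 256, (64, 64), dtype=np.uint8))
    b = GreyImage(rng.integers(0, 256, (64, 64), dtype=np.uint8))
    return a, b


@pytest.fixture(scope="session")
def default_sample():
    """A small synthetic section with an epithelium-biased and a hotspot marker."""
    params = SectionParams(
        markers=(
            MarkerConfig("Sdc1", domain_pct=30.0, epithelial_bias=1.5),
            MarkerConfig("CD45", domain_pct=20.0, hotspot_center=(0.6, 0.5)),
        ),
    )
    return generate_section(params, seed=11)


@pytest.fixture(scope="session")
def clean_sample():
    """Synthetic section with a perfectly dark background (no salt)."""
    params = SectionParams(background_salt_pct=0.0)
    return generate_section(params, seed=5)
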