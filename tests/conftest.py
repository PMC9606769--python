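import numpy as np
import pytest

from sipscape.sips import SIPConfig
from sipscape.stimuli import RandomPhaseSpec, synthesize_colored_random_phase
from sipscape.synth import generate_pseudo_painting


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_config():
    """SIP parameters scaled for 64×64 oracle comparisons."""
    return SIPConfig(
        resolution=64,
        n_edges=600,
        max_pairs=2_000_000,  # exhaustive pair enumeration at this edge count
        pair_seed=7,
    )


@pytest.fixture(scope="session")
def random_phase_64():
    spec = RandomPhaseSpec(size_px=64, set_slope=-2.0, seed=11)
    return synthesize_colored_random_phase(spec)


@pytest.fixture(scope="session")
def collage_64():
    g = np.random.default_rng(42)
    return generate_pseudo_painting(
        64, g, patch_scale=0.15, hue_spread=0.25, saturation=0.8, n_patches=40
    )


@pytest.fixture(scope="session")
def gradient_image_64():
    """Smooth two-direction ramp with a texture overlay; every cell non-flat."""
    g = np.random.default_rng(3)
    yy, xx = np.mgrid[0:64, 0:64] / 64.0
    base = np.stack([0.3 + 0.4 * xx, 0.5 * np.ones_like(xx), 0.2 + 0.5 * yy], axis=-1)
    return np.clip(base + 0.1 * g.standard_normal((64, 64, 3)), 0, 1)
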