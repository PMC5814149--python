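import numpy as np
import pytest

from monoaster.model import ModelParams
from monoaster.synthdata import Optics


@pytest.fixture
def control_params() -> ModelParams:
    """Control-monopole regime: short, fast-turning-over microtubules."""
    return ModelParams(ell=8.0, ell_u=24.9, alpha=2.38, rho0=4058.0, theta=0.05)


@pytest.fixture
def mcak_params() -> ModelParams:
    """MCAK-inhibited regime: threefold longer and more stable microtubules."""
    return ModelParams(ell=24.0, ell_u=24.9, alpha=2.38, rho0=4058.0, theta=0.016)


@pytest.fixture
def small_optics() -> Optics:
    """Noise-free rendering on a modest field, for fast forward models."""
    return Optics(pixel_size=0.35, size=420, noise="none", frame_interval=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
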