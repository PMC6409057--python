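import numpy as np
import pytest

import drls


@pytest.fixture(scope="session")
def reference_phantom():
    """Noiseless sharp sphere phantom: radius 15, contrast 60."""
    spec = drls.PhantomSpec(
        equiv_radius=15,
        intensity_bg=100.0,
        intensity_fg=40.0,
        noise_sigma=0.0,
        edge_blur_sigma=0.0,
        seed=1,
    )
    vol, gt = drls.generate_phantom(spec)
    return vol, gt, spec


@pytest.fixture(scope="session")
def small_phantom():
    """Small, fast phantom for evolution smoke tests (48^3, radius 10)."""
    spec = drls.PhantomSpec(
        shape=(48, 48, 48),
        equiv_radius=10,
        intensity_bg=100.0,
        intensity_fg=40.0,
        noise_sigma=0.0,
        edge_blur_sigma=0.0,
        seed=7,
    )
    vol, gt = drls.generate_phantom(spec)
    return vol, gt, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
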