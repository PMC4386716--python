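import numpy as np
import pytest

import camoband as cb
from camoband.synthetic import LEAF_BACKGROUND


@pytest.fixture(scope="session")
def default_scene():
    """Default desk-scale scene: 64x64x100, one window at 700 nm, separation 5."""
    return cb.leaf_scene(seed=11)


@pytest.fixture(scope="session")
def default_cube(default_scene):
    return cb.make_cube(default_scene)


@pytest.fixture(scope="session")
def noise_free_scene():
    """Noiseless scene with an explicit foreground bump: exactly two spectra."""
    return cb.SceneSpec(
        seed=3,
        noise_sd=0.0,
        foreground=LEAF_BACKGROUND.with_bumps([(700.0, 25.0, 0.08)]),
    )


@pytest.fixture(scope="session")
def noise_free_cube(noise_free_scene):
    return cb.make_cube(noise_free_scene)


@pytest.fixture
def tiny_cube():
    """4 lines x 3 samples x 5 bands, deterministic content."""
    rng = np.random.default_rng(7)
    data = rng.integers(0, 4096, size=(4, 3, 5)).astype(np.uint16)
    wl = np.array([400.0, 402.8, 405.6, 408.4, 411.2])
    return cb.Hypercube(data, wl, {"bit_depth": 12})
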