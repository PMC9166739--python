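import numpy as np
import pytest

import synaptoscope as ss


@pytest.fixture(scope="session")
def sparse_scene():
    """Well-separated mixed-class scene used by detection/quantification tests.

    Spacing exceeds twice the competing distance and peak standardized
    amplitude is far above the noise tolerance (SNR >> 10).
    """
    spec = ss.SceneSpec(
        field_px=(512, 512),
        counts={"A_only": 4, "B_only": 4, "AB": 4},
        offset_um=(0.3, 0.05),
        min_separation_px=100.0,
        seed=11,
    )
    particles, frame = ss.make_scene(spec)
    return spec, particles, frame


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def render_single_spot(shape=(128, 128), x=64.0, y=64.0, sigma=1.5,
                       total=5000.0, background=100.0, noise_sd=0.0, seed=0):
    """Minimal single-spot frame for closed-form checks."""
    from synaptoscope.synthetic import _add_spot

    rng = np.random.default_rng(seed)
    img = np.full(shape, background, dtype=float)
    _add_spot(img, x, y, sigma, total)
    if noise_sd > 0:
        img += rng.normal(0, noise_sd, shape)
    return img
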