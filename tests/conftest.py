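"""Shared fixtures: synthetic volumes and session-scoped phantoms.

The heavier phantoms are session-scoped so detection, matching and
end-to-end tests share one rendering pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import lungreg as lr
from lungreg.phantom import lung_mask


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture()
def ramp_volume():
    """I = 2x + 3y + 5z on a 24^3 grid, 1 mm spacing."""
    n = 24
    x, y, z = np.meshgrid(*(np.arange(n, dtype=float),) * 3, indexing="ij")
    return lr.Volume(2 * x + 3 * y + 5 * z)


@pytest.fixture()
def random_volume(rng):
    return lr.Volume(rng.normal(size=(12, 12, 12)))


@pytest.fixture(scope="session")
def phantom_noiseless():
    """Default 96^3 phantom pair, noise off (for detectability/ground truth)."""
    spec = lr.PhantomSpec(noise_sigma=0.0)
    template, target, lm_t, lm_g = lr.make_phantom(spec)
    return spec, template, target, lm_t, lm_g


@pytest.fixture(scope="session")
def phantom_default():
    """Default 96^3 phantom pair with the stated noise level, fixed seed."""
    spec = lr.PhantomSpec(seed=7)
    template, target, lm_t, lm_g = lr.make_phantom(spec)
    return spec, template, target, lm_t, lm_g


@pytest.fixture(scope="session")
def registration_result(phantom_default):
    """One full registration of the default phantom, shared across tests."""
    spec, template, target, lm_t, lm_g = phantom_default
    cfg = lr.PipelineConfig(mask_lo=0.0, mask_hi=550.0)
    return cfg, lr.register(
        template,
        target,
        cfg,
        landmarks_template=lr.LandmarkSet(lm_t),
        landmarks_target=lr.LandmarkSet(lm_g),
    )


@pytest.fixture(scope="session")
def detected_keypoints(phantom_noiseless):
    spec, template, _, _, _ = phantom_noiseless
    kps, response = lr.detect_keypoints(template, mask=lung_mask(spec))
    return template, kps, response
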