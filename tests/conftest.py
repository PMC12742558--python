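"""Shared fixtures: small synthetic volumes, a desk-scale phantom series and
a fitted velocity field, generated programmatically (no stored data)."""

from __future__ import annotations

import numpy as np
import pytest

import cptmorph as cm
from cptmorph.phantom import PhantomSpec


def small_phantom_spec(seed: int = 11, **overrides) -> PhantomSpec:
    """A 32^3 phantom proportioned like the 64^3 default (half scale)."""
    base = dict(noise_sd=5.0, n_landmarks=20)
    base.update(overrides)
    return cm.default_spec(seed=seed, shape=(32, 32, 32), **base)


@pytest.fixture(scope="session")
def phantom32() -> cm.PhantomSeries:
    return cm.generate(small_phantom_spec(), [0.0, 0.5, 1.0])


@pytest.fixture(scope="session")
def ldd_fit32(phantom32):
    """A short LDD fit on the 32^3 phantom, shared by the slower tests."""
    from cptmorph.presets import demo_config

    cfg = demo_config("ldd", scale="small", seed=3)
    model = cm.CPTRegistration(phantom32.frames[0], phantom32.frames[-1], config=cfg)
    return model.fit()


@pytest.fixture
def smooth_pair():
    """A smooth random fixed/moving volume pair on a 20^3 grid."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(7)
    shape = (20, 20, 20)
    fixed = cm.ImageVolume(gaussian_filter(rng.uniform(0, 1, shape), 2.0))
    moving = cm.ImageVolume(gaussian_filter(rng.uniform(0, 1, shape), 2.0))
    return fixed, moving


@pytest.fixture
def ramp_volume():
    """Volume with the affine intensity field f(i,j,k) = 2i + 3j + 5k."""
    idx = np.indices((12, 13, 14)).astype(np.float64)
    return cm.ImageVolume(2 * idx[0] + 3 * idx[1] + 5 * idx[2])


def make_constant_velocity_field(c, time_dependent: bool = True):
    """A SirenField rigged to output the constant vector c (voxel units)."""
    cfg = cm.SirenConfig(
        n_hidden_layers=1, width=4, omega0=1.0, time_dependent=time_dependent,
        output_scale=(1.0, 1.0, 1.0),
    )
    f = cm.SirenField(cfg, seed=0)
    for p in f.params:
        p[...] = 0.0
    f.params[-1][...] = np.asarray(c, dtype=np.float64)
    return f


def zero_last_layer(field: cm.SirenField) -> cm.SirenField:
    field.params[-1][...] = 0.0
    field.params[-2][...] = 0.0
    return field
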