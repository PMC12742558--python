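"""Desk-scale demonstration configurations.

The reference configuration (the :class:`RegistrationConfig` defaults —
3000 steps, 10 000-voxel batches, a width-256 network with omega0 = 48) is
sized for clinical volumes on a GPU. The presets here are the package's own
down-scaled problem sizes for the bundled synthetic phantoms, chosen so a
complete fit runs in minutes on one CPU core: a narrower network, a lower
first-layer frequency matched to the phantoms' smooth motion, larger
learning rate for the shorter schedule, and smaller batches. Everything
structural (four hidden sine layers, T = 4, symmetric LDD objective,
lambda2 = 1e-4, warmup + cosine schedule) is unchanged.
"""

from __future__ import annotations

from .model import RegistrationConfig

__all__ = ["demo_config"]

_SCALES = {
    # width, omega0, total_steps, warmup, batch, lr_peak per phantom scale
    "small": dict(width=48, omega0=12.0, total_steps=250, warmup_steps=40,
                  batch_size=1200, lr_peak=1e-3),
    "default": dict(width=64, omega0=12.0, total_steps=300, warmup_steps=50,
                    batch_size=2000, lr_peak=1e-3),
}


def demo_config(mode: str = "ldd", scale: str = "default", seed: int = 0,
                **overrides) -> RegistrationConfig:
    """A registration configuration sized for the synthetic phantoms.

    ``scale="small"`` targets 32^3 phantoms (used by the fast tests),
    ``scale="default"`` the 64^3 default phantom.
    """
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(_SCALES)}")
    kw = dict(_SCALES[scale])
    kw.update(overrides)
    return RegistrationConfig(mode=mode, T=4, seed=seed, **kw)
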