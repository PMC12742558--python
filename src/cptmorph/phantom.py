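"""Synthetic 4D motion phantoms with analytically known trajectories.

The phantom emulates the structure of a respiratory 4DCT study at desk
scale: piecewise-smooth HU-valued anatomy (soft-edged ellipsoids on an air
background), a time-continuous nonlinear motion model, landmark pairs, per
structure masks, and — optionally — a sliding interface with
equal-and-opposite tangential motion on either side of a plane
(discontinuous across it, smooth within each side), the classic failure mode
of globally smooth regularizers.

Motion is defined as an analytic velocity field

    v(x, t) = sum_b A_b * exp(-|x - c_b|^2 / (2 sigma_b^2)) * p'(t)
              [+ side(x) * a_slide * p'(t)]

with a linear (p(t) = t) or sinusoidal (p(t) = sin^2(pi t / 2), an
inhale-to-exhale ramp) temporal profile. Trajectories have no closed form in
general, so ground truth is produced by a fine-step Euler oracle (1024 steps
over the unit interval by default). Frames are rendered analytically at each
time — each voxel's intensity is looked up at its back-tracked position in
the reference anatomy — so rendering error is independent of any warping
code under test. Landmark transport and frame rendering use one and the same
motion oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .core import ImageVolume, LandmarkSet, RegionMask, voxel_grid_points

__all__ = [
    "Ellipsoid",
    "GaussianBump",
    "SlidingPlane",
    "PhantomSpec",
    "MotionModel",
    "PhantomSeries",
    "generate",
    "true_displacement",
    "default_spec",
]


@dataclass(frozen=True)
class Ellipsoid:
    """A soft-edged ellipsoid structure: center/radii in voxels, intensity in HU."""

    center: tuple
    radii: tuple
    intensity: float
    edge: float = 0.04  # softness of the boundary, in units of the radial coordinate


@dataclass(frozen=True)
class GaussianBump:
    """One motion component: amplitude vector (voxels) with Gaussian support."""

    center: tuple
    amplitude: tuple
    sigma: float


@dataclass(frozen=True)
class SlidingPlane:
    """Equal-and-opposite tangential offsets on the two sides of a plane.

    ``normal`` defines the plane through ``point`` (volume center if None);
    ``offset`` is the per-side displacement amplitude in voxels and is
    projected onto the plane so the motion is strictly tangential (particles
    never cross the interface).
    """

    normal: tuple
    offset: tuple
    point: tuple | None = None


@dataclass
class PhantomSpec:
    """Full description of a synthetic 4D study."""

    shape: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)
    background: float = -1000.0
    structures: list = dc_field(default_factory=list)
    bumps: list = dc_field(default_factory=list)
    temporal_profile: str = "sinusoidal"  # or "linear"
    sliding: SlidingPlane | None = None
    noise_sd: float = 10.0
    n_landmarks: int = 50
    seed: int = 0
    oracle_steps: int = 1024

    def __post_init__(self) -> None:
        if self.temporal_profile not in ("linear", "sinusoidal"):
            raise ValueError(f"unknown temporal profile {self.temporal_profile!r}")
        if self.noise_sd < 0 or self.n_landmarks < 0 or self.oracle_steps < 1:
            raise ValueError("noise_sd, n_landmarks >= 0 and oracle_steps >= 1 required")
        for s in self.structures:
            if any(r <= 0 for r in s.radii):
                raise ValueError("ellipsoid radii must be positive")
        for b in self.bumps:
            if b.sigma <= 0:
                raise ValueError("bump sigma must be positive")


def default_spec(seed: int = 0, shape=(64, 64, 64), **overrides) -> PhantomSpec:
    """The default desk-scale phantom: 64^3, 1 mm spacing, a lung-like
    ellipsoid (-800 HU) holding a tumor-like one (+50 HU) on a -1000 HU
    background, one Gaussian motion bump of 5 voxels peak amplitude with a
    sinusoidal (inhale-to-exhale) profile, 10 HU noise, 50 landmarks.

    Other ``shape`` values scale the whole geometry (structures, motion
    amplitude, bump width) proportionally.
    """
    f = np.asarray(shape, dtype=np.float64) / 64.0
    fm = float(f.mean())
    spec = PhantomSpec(
        shape=tuple(shape),
        structures=[
            Ellipsoid(tuple((32, 32, 30) * f), tuple((18, 14, 16) * f), -800.0),
            Ellipsoid(tuple((36, 34, 32) * f), tuple((5, 5, 5) * f), 50.0),
        ],
        bumps=[
            GaussianBump(tuple((32, 32, 30) * f), tuple((0.0, 1.5, 5.0) * f), 14.0 * fm)
        ],
        seed=seed,
    )
    from dataclasses import replace

    return replace(spec, **overrides) if overrides else spec


class MotionModel:
    """The analytic velocity field and its fine-step trajectory oracle."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self._centers = np.array([b.center for b in spec.bumps], dtype=np.float64)
        self._amps = np.array([b.amplitude for b in spec.bumps], dtype=np.float64)
        self._sigmas = np.array([b.sigma for b in spec.bumps], dtype=np.float64)
        if spec.sliding is not None:
            n = np.asarray(spec.sliding.normal, dtype=np.float64)
            n = n / np.linalg.norm(n)
            off = np.asarray(spec.sliding.offset, dtype=np.float64)
            self._slide_normal = n
            self._slide_offset = off - (off @ n) * n  # strictly tangential
            pt = spec.sliding.point
            self._slide_point = (
                np.asarray(pt, dtype=np.float64)
                if pt is not None
                else (np.asarray(spec.shape, dtype=np.float64) - 1.0) / 2.0
            )
        else:
            self._slide_normal = None

    def profile_rate(self, t: float) -> float:
        """p'(t) of the temporal profile."""
        if self.spec.temporal_profile == "linear":
            return 1.0
        return 0.5 * math.pi * math.sin(math.pi * t)

    def profile(self, t: float) -> float:
        if self.spec.temporal_profile == "linear":
            return t
        return math.sin(0.5 * math.pi * t) ** 2

    def velocity(self, x, t: float) -> np.ndarray:
        """Analytic velocity (voxels per unit time) at voxel coordinates x."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        v = np.zeros_like(x)
        rate = self.profile_rate(t)
        for c, a, s in zip(self._centers, self._amps, self._sigmas):
            d2 = np.sum((x - c) ** 2, axis=1)
            v += np.exp(-d2 / (2.0 * s * s))[:, None] * a
        if self._slide_normal is not None:
            side = np.sign((x - self._slide_point) @ self._slide_normal)
            v = v + side[:, None] * self._slide_offset
        return v * rate

    def displacement(self, x, t0: float, t1: float) -> np.ndarray:
        """Oracle displacement by fine-step Euler integration of the velocity."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        span = abs(t1 - t0)
        if span == 0.0:
            return np.zeros_like(x)
        k = max(1, math.ceil(self.spec.oracle_steps * span - 1e-9))
        dt = (t1 - t0) / k
        pos = x.copy()
        t = t0
        for _ in range(k):
            pos += self.velocity(pos, t) * dt
            t += dt
        return pos - x

    def map(self, x, t0: float, t1: float) -> np.ndarray:
        return np.atleast_2d(np.asarray(x, dtype=np.float64)) + self.displacement(x, t0, t1)


@dataclass
class PhantomSeries:
    """Rendered frames, ground-truth motion, landmarks and masks."""

    spec: PhantomSpec
    times: list
    frames: list  # ImageVolume per time
    landmarks: list  # LandmarkSet per time (transported by the oracle)
    masks: list  # RegionMask per structure, at t = 0
    motion: MotionModel

    def frame_at(self, t: float) -> ImageVolume:
        for tt, f in zip(self.times, self.frames):
            if tt == t:
                return f
        raise KeyError(f"no frame generated at t={t}")

    def landmarks_at(self, t: float) -> LandmarkSet:
        for tt, lm in zip(self.times, self.landmarks):
            if tt == t:
                return lm
        raise KeyError(f"no landmarks at t={t}")

    def mask_at(self, structure: int, t: float) -> RegionMask:
        """Indicator of one structure transported to time t (oracle-exact)."""
        return _structure_mask(self.spec, self.motion, structure, t)


def _radial(spec: PhantomSpec, s: Ellipsoid, pts: np.ndarray) -> np.ndarray:
    c = np.asarray(s.center, dtype=np.float64)
    r = np.asarray(s.radii, dtype=np.float64)
    return np.sqrt(np.sum(((pts - c) / r) ** 2, axis=1))


def _render(spec: PhantomSpec, motion: MotionModel, t: float) -> np.ndarray:
    """Intensity at time t: anatomy looked up at the back-tracked position."""
    grid = voxel_grid_points(spec.shape)
    ref = grid + motion.displacement(grid, t, 0.0) if t != 0.0 else grid
    vals = np.full(grid.shape[0], spec.background)
    for s in spec.structures:
        q = _radial(spec, s, ref)
        alpha = 1.0 / (1.0 + np.exp((q - 1.0) / s.edge))
        vals = vals * (1.0 - alpha) + s.intensity * alpha
    return vals.reshape(spec.shape)


def _structure_mask(spec: PhantomSpec, motion: MotionModel, index: int, t: float) -> RegionMask:
    s = spec.structures[index]
    grid = voxel_grid_points(spec.shape)
    ref = grid + motion.displacement(grid, t, 0.0) if t != 0.0 else grid
    return RegionMask((_radial(spec, s, ref) <= 1.0).reshape(spec.shape))


def _check_in_bounds(spec: PhantomSpec, motion: MotionModel, times) -> None:
    hi = np.asarray(spec.shape, dtype=np.float64) - 1.0
    for t in times:
        for s in spec.structures:
            c = np.asarray(s.center, dtype=np.float64)
            r = np.asarray(s.radii, dtype=np.float64)
            corners = c + np.array([-1.0, 1.0])[:, None] * r
            moved = corners + motion.displacement(corners, 0.0, t)
            if np.any(moved < 0) or np.any(moved > hi):
                raise ValueError(
                    f"structure at {s.center} leaves the volume at t={t}"
                )


def generate(spec: PhantomSpec, times) -> PhantomSeries:
    """Render the phantom series at the requested times in [0, 1].

    Frames are rendered analytically (never by warping frame 0); landmarks
    are sampled inside the first structure at t = 0 and transported by the
    same oracle; seeded noise is added last, so the same seed yields a
    bit-identical series.
    """
    times = [float(t) for t in times]
    if sorted(times) != times or any(not (0.0 <= t <= 1.0) for t in times):
        raise ValueError("times must be sorted and within [0, 1]")
    if not spec.structures:
        raise ValueError("spec must contain at least one structure")
    motion = MotionModel(spec)
    _check_in_bounds(spec, motion, times)
    rng = np.random.default_rng(spec.seed)

    # landmarks: rejection-sample inside the first structure at t = 0
    lm0 = np.empty((spec.n_landmarks, 3))
    s0 = spec.structures[0]
    count = 0
    while count < spec.n_landmarks:
        cand = rng.uniform(
            np.asarray(s0.center) - np.asarray(s0.radii),
            np.asarray(s0.center) + np.asarray(s0.radii),
            size=(max(8, spec.n_landmarks), 3),
        )
        keep = cand[_radial(spec, s0, cand) <= 0.85]
        take = min(len(keep), spec.n_landmarks - count)
        lm0[count : count + take] = keep[:take]
        count += take

    frames, landmark_sets = [], []
    for t in times:
        vals = _render(spec, motion, t)
        if spec.noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.shape)
        frames.append(ImageVolume(vals, np.asarray(spec.spacing, dtype=np.float64)))
        if spec.n_landmarks:
            pts = lm0 + motion.displacement(lm0, 0.0, t) if t != 0.0 else lm0.copy()
        else:
            pts = np.empty((0, 3))
        lms = LandmarkSet(pts, frame_label=f"t={t:g}")
        if spec.n_landmarks:
            lms.check_in_bounds(spec.shape)
        landmark_sets.append(lms)

    masks = [_structure_mask(spec, motion, i, 0.0) for i in range(len(spec.structures))]
    return PhantomSeries(spec, times, frames, landmark_sets, masks, motion)


def true_displacement(series: PhantomSeries, x, t0: float, t1: float) -> np.ndarray:
    """Ground-truth displacement of points x (voxel coords) from t0 to t1."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    hi = np.asarray(series.spec.shape, dtype=np.float64) - 1.0
    if np.any(x < 0) or np.any(x > hi):
        raise ValueError("points outside the volume bounds")
    return series.motion.displacement(x, t0, t1)
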