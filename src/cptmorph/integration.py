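"""Euler integration of the velocity field into trajectories and DVFs.

The displacement map between two times is the time integral of the velocity
field along each particle's own trajectory (the Lagrangian view), estimated
with the explicit (left-endpoint) Euler recursion

    x_{k+1} = x_k + v(x_k, t_k) * dt.

``T`` fixes the step budget for the whole unit interval: a sub-interval
[t0, t1] is integrated with ceil(T * |t1 - t0|) steps so the step length
never exceeds 1/T and the numerical error stays uniform across all query
times. Reverse-time integration (t1 < t0) uses the same recursion with a
negative dt — the velocity field reverses directly, no second model or map
inversion is needed.

Integration runs in continuous voxel coordinates; positions are converted to
normalized [-1, 1] coordinates only to evaluate the network. Mid-trajectory
points may leave the [-1, 1]^3 domain (the sine network is globally defined);
a guard box at ``guard_factor`` times the domain flags runaway trajectories
instead of silently clamping them.

``integrate_with_tape`` / ``backprop_integration`` implement reverse-mode
differentiation through the whole Euler loop (backpropagation through time),
used by the training objective.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, voxel_grid_points, voxel_to_normalized
from .siren import SirenField

__all__ = [
    "Trajectory",
    "DenseDVF",
    "GuardBoxWarning",
    "integrate",
    "displacement_map",
    "dense_dvf",
    "integrate_with_tape",
    "backprop_integration",
]


class GuardBoxWarning(UserWarning):
    """A trajectory left the guard box around the image domain."""


@dataclass
class Trajectory:
    """Ordered (t, position) samples of one particle under Euler integration.

    ``times`` is strictly monotone (increasing forward, decreasing reverse);
    positions are continuous voxel indices.
    """

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        d = np.diff(self.times)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("trajectory times must be strictly monotone")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("trajectory positions must be finite")


@dataclass
class DenseDVF:
    """Displacement vectors (voxel units) sampled on a reference grid."""

    vectors: np.ndarray  # (n0, n1, n2, 3)
    t0: float
    t1: float
    steps_T: int

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("DVF must have shape (n0, n1, n2, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("DVF contains non-finite vectors")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def mapped_points(self) -> np.ndarray:
        """identity + displacement, as an (n0, n1, n2, 3) coordinate array."""
        shape = self.grid_shape
        grid = voxel_grid_points(shape).reshape(*shape, 3)
        return grid + self.vectors


def _step_plan(t0: float, t1: float, T: int) -> tuple[int, float]:
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0.0 <= t0 <= 1.0 and 0.0 <= t1 <= 1.0):
        raise ValueError("t0 and t1 must lie in [0, 1]")
    span = abs(t1 - t0)
    if span == 0.0:
        return 0, 0.0
    # tolerate float fuzz so T * span that is an exact integer stays exact
    n_steps = max(1, math.ceil(T * span - 1e-9))
    return n_steps, (t1 - t0) / n_steps


def integrate(
    field: SirenField,
    x0,
    t0: float,
    t1: float,
    T: int,
    shape,
    guard_factor: float = 1.5,
    trajectories: bool = True,
):
    """Euler-integrate particles of the velocity field from t0 to t1.

    Parameters
    ----------
    x0 : (N, 3) array
        Start positions in continuous voxel indices.
    shape : grid shape used for the normalized-coordinate conversion.

    Returns
    -------
    endpoints : (N, 3) array of voxel coordinates at t1.
    trajs : list of :class:`Trajectory` (empty when ``trajectories=False``).
    """
    x = np.atleast_2d(np.asarray(x0, dtype=np.float64)).copy()
    n_steps, dt = _step_plan(t0, t1, T)
    ts = [t0]
    path = [x.copy()] if trajectories else None
    t = t0
    escaped = False
    for _ in range(n_steps):
        xn = voxel_to_normalized(x, shape)
        if not escaped and np.any(np.abs(xn) > guard_factor):
            escaped = True
        v = field.eval_velocity(xn, t)
        x = x + v * dt
        t += dt
        if trajectories:
            ts.append(t)
            path.append(x.copy())
    if escaped:
        warnings.warn(
            "trajectory left the guard box (|normalized coord| > "
            f"{guard_factor}); results may extrapolate far outside the image",
            GuardBoxWarning,
            stacklevel=2,
        )
    trajs = []
    if trajectories and n_steps > 0:
        stacked = np.stack(path, axis=0)  # (K+1, N, 3)
        tarr = np.asarray(ts)
        trajs = [Trajectory(tarr, stacked[:, i]) for i in range(x.shape[0])]
    elif trajectories:
        trajs = [Trajectory(np.array([t0]), x[i : i + 1]) for i in range(x.shape[0])]
    return x, trajs


def displacement_map(field: SirenField, points, t0: float, t1: float, T: int, shape):
    """Displacement vectors endpoint - start for a batch of voxel-index points.

    For a spatial-only (time-independent, E2E-style) field this is a direct
    network evaluation with no time integration.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if not field.time_dependent and t0 == 0.0 and t1 == 1.0:
        return field.eval_displacement(voxel_to_normalized(points, shape))
    end, _ = integrate(field, points, t0, t1, T, shape, trajectories=False)
    return end - points


def dense_dvf(
    field: SirenField,
    reference: ImageVolume,
    t0: float,
    t1: float,
    T: int,
    chunk_size: int = 65536,
) -> DenseDVF:
    """Displacement map evaluated at every voxel center of the reference grid.

    Processes the grid in chunks; chunked and whole-grid evaluation are
    bit-identical because each point's integration is independent.
    """
    shape = reference.shape
    grid = voxel_grid_points(shape)
    out = np.empty_like(grid)
    for lo in range(0, grid.shape[0], chunk_size):
        hi = min(lo + chunk_size, grid.shape[0])
        out[lo:hi] = displacement_map(field, grid[lo:hi], t0, t1, T, shape)
    return DenseDVF(out.reshape(*shape, 3), t0=t0, t1=t1, steps_T=T)


# ----------------------------------------------------------------------
# differentiable integration (backpropagation through time)


@dataclass
class IntegrationTape:
    """Forward records of one Euler integration, for the reverse pass."""

    xs: list  # per-step positions (voxel coords), length K+1
    net_tapes: list  # per-step network tapes, length K
    vels: np.ndarray | None  # (K, N, 3) velocities, voxel units / unit time
    dt: float
    t0: float
    shape: tuple


def integrate_with_tape(field: SirenField, x0, t0: float, t1: float, T: int, shape):
    """Euler integration that records everything needed for backprop.

    Returns (endpoints, tape). Works for time-dependent and stationary
    velocity fields alike.
    """
    x = np.atleast_2d(np.asarray(x0, dtype=np.float64))
    n_steps, dt = _step_plan(t0, t1, T)
    shape = tuple(shape)
    xs = [x]
    net_tapes = []
    vels = []
    t = t0
    for _ in range(n_steps):
        xn = voxel_to_normalized(x, shape)
        if field.time_dependent:
            tcol = np.full((x.shape[0], 1), 2.0 * t - 1.0)
            inp = np.concatenate([xn, tcol], axis=1)
        else:
            inp = xn
        v, tape = field.forward(inp, want_tape=True)
        net_tapes.append(tape)
        vels.append(v)
        x = x + v * dt
        xs.append(x)
        t += dt
    vel_arr = np.stack(vels, axis=0) if vels else None
    return x, IntegrationTape(xs, net_tapes, vel_arr, dt, t0, shape)


def backprop_integration(
    field: SirenField,
    tape: IntegrationTape,
    d_end: np.ndarray,
    d_vels: np.ndarray | None = None,
    grads: list | None = None,
):
    """Reverse pass through an Euler integration.

    Parameters
    ----------
    d_end : (N, 3)
        Cotangent of the endpoint positions (dL/dx_end, voxel units).
    d_vels : (K, N, 3), optional
        Extra cotangent on each step's velocity (e.g. from a velocity-norm
        regularizer).

    Returns (grads, d_x0): accumulated parameter gradients and the cotangent
    of the start positions.
    """
    if grads is None:
        grads = field.zero_grads()
    g = np.asarray(d_end, dtype=np.float64).copy()
    scale = 2.0 / (np.asarray(tape.shape, dtype=np.float64) - 1.0)  # d xnorm / d xvox
    K = len(tape.net_tapes)
    for k in range(K - 1, -1, -1):
        dv = g * tape.dt
        if d_vels is not None:
            dv = dv + d_vels[k]
        _, d_in = field.backward(tape.net_tapes[k], dv, grads=grads)
        g = g + d_in[:, :3] * scale
    return grads, g
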