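"""Similarity and regularization terms composing the training objectives.

Two objectives are supported:

* spatial-only (E2E): negative NCC between the fixed image and the moving
  image warped by ``x + g(x)``, optionally plus a folding penalty on the
  Jacobian determinant of the map (lambda1) and weight decay (lambda3);
* spatio-temporal (LDD): the symmetric objective — negative NCC in both
  directions, with the forward map obtained by Euler integration of the
  velocity field 0 -> 1 and the reverse map by direct reverse-time
  integration 1 -> 0 — plus an L2 penalty on the velocity samples along the
  integration steps (lambda2, the default and only active regularizer),
  and optionally lambda1 / lambda3 as above.

Images entering the similarity terms are expected to be intensity-normalized
by the caller (the model rescales a configured HU window to [0, 1]); NCC is
invariant under positive affine intensity maps, so the optimum is unchanged.

All terms provide hand-written exact gradients (reverse mode); the folding
penalty differentiates a central-difference Jacobian of the map, which keeps
the whole computation first-order in network derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, normalized_to_voxel, trilinear_sample_grad
from .integration import backprop_integration, integrate_with_tape
from .siren import SirenField

__all__ = [
    "LossWeights",
    "VoxelBatch",
    "ncc",
    "jacobian_determinants",
    "vvf_l2_penalty",
    "loss_e2e",
    "loss_ldd",
]

_NCC_EPS = 1e-8


@dataclass(frozen=True)
class LossWeights:
    """Regularizer strengths (all >= 0).

    lambda1 weighs the folding penalty on the displacement map, lambda2 the
    L2 norm of the velocity samples (LDD only), lambda3 weight decay on the
    network parameters. Defaults activate only lambda2.
    """

    lambda1: float = 0.0
    lambda2: float = 1e-4
    lambda3: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class VoxelBatch:
    """A mini-batch of voxel centers with their reference intensities.

    ``points`` are normalized [-1, 1] coordinates on the reference grid;
    ``fixed_values`` the (normalized) intensities of the reference image at
    those voxels.
    """

    points: np.ndarray
    fixed_values: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.fixed_values = np.asarray(self.fixed_values, dtype=np.float64).ravel()
        if self.points.shape[0] != self.fixed_values.shape[0]:
            raise ValueError("points / fixed_values length mismatch")
        if np.any(np.abs(self.points) > 1.0 + 1e-9):
            raise ValueError("batch points must lie within [-1, 1]^3")

    @property
    def batch_size(self) -> int:
        return self.points.shape[0]


def _ncc_with_grad(a: np.ndarray, b: np.ndarray):
    """Zero-normalized cross-correlation and its gradient w.r.t. b."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("ncc requires two equal-length batches of size >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    sa = np.sqrt(ac @ ac + _NCC_EPS)
    sb = np.sqrt(bc @ bc + _NCC_EPS)
    sab = ac @ bc
    val = sab / (sa * sb)
    grad_b = ac / (sa * sb) - val * bc / (sb * sb)
    return val, grad_b


def ncc(a, b) -> float:
    """Zero-normalized cross-correlation of two intensity batches, in [-1, 1].

    Mean-centered dot product divided by the (epsilon-stabilized) product of
    standard deviations, computed globally over the batch. The training loss
    is ``-ncc``.
    """
    val, _ = _ncc_with_grad(a, b)
    return float(val)


def _adjugate_3x3(J: np.ndarray) -> np.ndarray:
    """Transposed cofactor matrices of a (N, 3, 3) stack: d det / d J."""
    C = np.empty_like(J)
    a = J
    C[:, 0, 0] = a[:, 1, 1] * a[:, 2, 2] - a[:, 1, 2] * a[:, 2, 1]
    C[:, 0, 1] = -(a[:, 1, 0] * a[:, 2, 2] - a[:, 1, 2] * a[:, 2, 0])
    C[:, 0, 2] = a[:, 1, 0] * a[:, 2, 1] - a[:, 1, 1] * a[:, 2, 0]
    C[:, 1, 0] = -(a[:, 0, 1] * a[:, 2, 2] - a[:, 0, 2] * a[:, 2, 1])
    C[:, 1, 1] = a[:, 0, 0] * a[:, 2, 2] - a[:, 0, 2] * a[:, 2, 0]
    C[:, 1, 2] = -(a[:, 0, 0] * a[:, 2, 1] - a[:, 0, 1] * a[:, 2, 0])
    C[:, 2, 0] = a[:, 0, 1] * a[:, 1, 2] - a[:, 0, 2] * a[:, 1, 1]
    C[:, 2, 1] = -(a[:, 0, 0] * a[:, 1, 2] - a[:, 0, 2] * a[:, 1, 0])
    C[:, 2, 2] = a[:, 0, 0] * a[:, 1, 1] - a[:, 0, 1] * a[:, 1, 0]
    return C


def jacobian_determinants(map_fn, points, h: float = 1e-3) -> np.ndarray:
    """Jacobian determinants of a point-to-point map at a batch of points.

    ``map_fn`` maps (N, 3) voxel coordinates to (N, 3) voxel coordinates
    (identity + displacement). Partials are estimated by central differences
    with step ``h`` in voxel units. For a map backed by the network itself,
    :meth:`SirenField.input_jacobian` gives the exact derivative; the two
    agree to O(h^2).
    """
    if h <= 0:
        raise ValueError("h must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    n = points.shape[0]
    J = np.empty((n, 3, 3))
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = h
        plus = np.asarray(map_fn(points + e), dtype=np.float64)
        minus = np.asarray(map_fn(points - e), dtype=np.float64)
        if not (np.all(np.isfinite(plus)) and np.all(np.isfinite(minus))):
            raise ValueError("map produced non-finite outputs")
        J[:, :, axis] = (plus - minus) / (2.0 * h)
    return np.linalg.det(J)


def vvf_l2_penalty(velocity_samples) -> float:
    """Sum over time steps of the mean squared velocity magnitude.

    ``velocity_samples`` is a sequence over time steps of (N, 3) velocity
    batches. Normalization: mean over points, sum over steps — the penalty
    scale is independent of batch size but tracks the step count.
    """
    samples = [np.atleast_2d(np.asarray(v, dtype=np.float64)) for v in velocity_samples]
    if not samples or any(v.size == 0 for v in samples):
        raise ValueError("vvf_l2_penalty needs at least one non-empty time step")
    return float(sum(np.mean(np.sum(v * v, axis=1)) for v in samples))


# ----------------------------------------------------------------------
# folding (negative-determinant) penalty with gradients


def _fold_penalty_fd(map_eval, points, h, grads_sink):
    """mean(relu(-det J)) of a differentiable map via central differences.

    ``map_eval(pts)`` must return (mapped, backward) where backward(d_mapped)
    routes the cotangent into the parameter gradients. Calls the map at the
    six offset stencils; contributes gradients only where det < 0.
    """
    n = points.shape[0]
    evals = []  # (mapped, backward) per stencil arm
    J = np.empty((n, 3, 3))
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = h
        mp, back_p = map_eval(points + e)
        mm, back_m = map_eval(points - e)
        evals.append((back_p, back_m))
        J[:, :, axis] = (mp - mm) / (2.0 * h)
    det = np.linalg.det(J)
    neg = det < 0.0
    penalty = float(np.mean(np.where(neg, -det, 0.0)))
    if grads_sink is not None and np.any(neg):
        dJ = np.zeros_like(J)
        dJ[neg] = -_adjugate_3x3(J[neg]) / n  # d penalty / d J
        for axis, (back_p, back_m) in enumerate(evals):
            d_col = dJ[:, :, axis] / (2.0 * h)
            back_p(d_col)
            back_m(-d_col)
    return penalty


def _weight_decay(field: SirenField, weights: LossWeights, grads):
    if weights.lambda3 == 0.0:
        return 0.0
    sq = sum(float(np.sum(p * p)) for p in field.params)
    if grads is not None:
        for g, p in zip(grads, field.params):
            g += 2.0 * weights.lambda3 * p
    return weights.lambda3 * sq


def loss_e2e(
    field: SirenField,
    fixed: ImageVolume,
    moving: ImageVolume,
    batch: VoxelBatch,
    weights: LossWeights = LossWeights(lambda2=0.0),
    want_grads: bool = False,
    jac_h: float = 0.5,
):
    """Spatial-only objective: -NCC(I0, I1 o (x + g(x))) + regularizers.

    Returns the scalar loss, or (loss, grads) with ``want_grads``.
    """
    if field.time_dependent:
        raise ValueError("loss_e2e requires a time-independent field")
    shape = fixed.shape
    grads = field.zero_grads() if want_grads else None

    def map_eval(pts_vox):
        from .core import voxel_to_normalized

        xn = voxel_to_normalized(pts_vox, shape)
        disp, tape = field.forward(xn, want_tape=True)
        mapped = pts_vox + disp

        def backward(d_mapped):
            if grads is not None:
                field.backward(tape, d_mapped, grads=grads)

        return mapped, backward

    x_vox = normalized_to_voxel(batch.points, shape)
    mapped, back = map_eval(x_vox)
    samp, sgrad = trilinear_sample_grad(moving, mapped)
    ncc_val, d_samp = _ncc_with_grad(batch.fixed_values, samp)
    loss = -ncc_val
    back(-d_samp[:, None] * sgrad)

    if weights.lambda1 > 0.0:
        loss += weights.lambda1 * _fold_penalty_fd(
            lambda p: _scaled_backward(map_eval, p, weights.lambda1),
            x_vox,
            jac_h,
            grads,
        )
    loss += _weight_decay(field, weights, grads)
    if want_grads:
        return loss, grads
    return loss


def _scaled_backward(map_eval, pts, lam):
    mapped, back = map_eval(pts)
    return mapped, (lambda d: back(lam * d))


def loss_ldd(
    field: SirenField,
    fixed: ImageVolume,
    moving: ImageVolume,
    batch_fwd: VoxelBatch,
    batch_bwd: VoxelBatch,
    T: int,
    weights: LossWeights = LossWeights(),
    want_grads: bool = False,
    jac_h: float = 0.5,
):
    """Symmetric spatio-temporal objective over both warp directions.

    -NCC(I0, I1 o phi_0->1) - NCC(I1, I0 o phi_1->0)
    + lambda1 [fold(phi_0->1) + fold(phi_1->0)]
    + lambda2 * velocity L2 penalty (both directions)
    + lambda3 ||params||^2.

    ``batch_fwd`` carries fixed-image voxels (integrated 0 -> 1 and compared
    against the moving image); ``batch_bwd`` moving-image voxels (integrated
    1 -> 0, against the fixed image). The reverse map comes from reversed
    integration of the same field — no second model.
    """
    shape = fixed.shape
    grads = field.zero_grads() if want_grads else None
    loss = 0.0

    for t0, t1, batch, target in (
        (0.0, 1.0, batch_fwd, moving),
        (1.0, 0.0, batch_bwd, fixed),
    ):
        x0 = normalized_to_voxel(batch.points, shape)
        x_end, tape = integrate_with_tape(field, x0, t0, t1, T, shape)
        samp, sgrad = trilinear_sample_grad(target, x_end)
        ncc_val, d_samp = _ncc_with_grad(batch.fixed_values, samp)
        loss += -ncc_val
        d_vels = None
        if weights.lambda2 > 0.0 and tape.vels is not None:
            loss += weights.lambda2 * vvf_l2_penalty(tape.vels)
            if grads is not None:
                # d/dv of lambda2 * mean_points sum_steps |v|^2
                d_vels = 2.0 * weights.lambda2 * tape.vels / batch.batch_size
        if grads is not None:
            d_end = -d_samp[:, None] * sgrad
            backprop_integration(field, tape, d_end, d_vels=d_vels, grads=grads)
        if weights.lambda1 > 0.0:

            def map_eval(pts, _t0=t0, _t1=t1):
                end, tp = integrate_with_tape(field, pts, _t0, _t1, T, shape)

                def backward(d_mapped):
                    if grads is not None:
                        backprop_integration(
                            field, tp, weights.lambda1 * d_mapped, grads=grads
                        )

                return end, backward

            loss += weights.lambda1 * _fold_penalty_fd(map_eval, x0, jac_h, grads)

    loss += _weight_decay(field, weights, grads)
    if want_grads:
        return loss, grads
    return loss
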