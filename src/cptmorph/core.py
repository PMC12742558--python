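"""Coordinate conventions, continuous sampling, and backward warping.

Everything downstream shares three conventions fixed here:

* voxel indices are 0-based and continuous; a volume of shape ``(n0, n1, n2)``
  spans indices ``[0, n_i - 1]`` per axis,
* network inputs live in normalized coordinates ``[-1, 1]`` per axis, with
  index 0 mapping to -1 and index ``n_i - 1`` mapping to +1,
* displacements are carried in voxel units internally and converted to mm
  (via the spacing vector) only inside metrics.

Sampling outside the volume uses a clamp-to-edge border: the border voxel is
replicated, which avoids injecting artificial air (background) intensity into
the similarity loss during optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageVolume",
    "LandmarkSet",
    "RegionMask",
    "voxel_to_normalized",
    "normalized_to_voxel",
    "trilinear_sample",
    "trilinear_sample_grad",
    "warp_image",
]


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical spacing and origin.

    Parameters
    ----------
    voxels : ndarray, shape (n0, n1, n2)
        Scalar intensities (HU for CT, arbitrary units otherwise).
    spacing : array_like of 3 floats
        Physical size of one voxel per axis, in mm. Strictly positive.
    origin : array_like of 3 floats, optional
        Physical position of voxel (0, 0, 0), in mm.
    """

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.voxels.copy(), self.spacing.copy(), self.origin.copy())


@dataclass
class LandmarkSet:
    """Point landmarks in continuous voxel-index units (0-based internally)."""

    points: np.ndarray
    frame_label: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[1] != 3:
            raise ValueError("landmarks must be N x 3")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmarks contain non-finite values")

    def __len__(self) -> int:
        return self.points.shape[0]

    def check_in_bounds(self, shape) -> None:
        hi = np.asarray(shape, dtype=np.float64) - 1.0
        if np.any(self.points < 0) or np.any(self.points > hi):
            raise ValueError("landmarks fall outside the volume bounds")


@dataclass
class RegionMask:
    """Binary region-of-interest on the same grid as a companion ImageVolume."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def check_aligned(self, volume: ImageVolume) -> None:
        if self.voxels.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match volume {volume.shape}"
            )


def _as_points(p) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    squeeze = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[-1] != 3:
        raise ValueError(f"points must have 3 components, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite coordinates")
    return p, squeeze


def voxel_to_normalized(p, shape) -> np.ndarray:
    """Map continuous voxel indices to normalized [-1, 1] coordinates.

    Axis ``i`` maps affinely so index 0 -> -1 and index ``shape[i]-1`` -> +1.
    """
    p, squeeze = _as_points(p)
    shape = np.asarray(shape, dtype=np.float64)
    if np.any(shape < 2):
        raise ValueError("shape components must be >= 2")
    out = 2.0 * p / (shape - 1.0) - 1.0
    return out[0] if squeeze else out


def normalized_to_voxel(x, shape) -> np.ndarray:
    """Inverse of :func:`voxel_to_normalized` (round-trips to machine precision)."""
    x, squeeze = _as_points(x)
    shape = np.asarray(shape, dtype=np.float64)
    if np.any(shape < 2):
        raise ValueError("shape components must be >= 2")
    out = (x + 1.0) * (shape - 1.0) / 2.0
    return out[0] if squeeze else out


def _gather(vox: np.ndarray, i0, i1, i2) -> np.ndarray:
    return vox[i0, i1, i2]


def _trilinear(vox: np.ndarray, p: np.ndarray, want_grad: bool):
    """Vectorized trilinear interpolation with clamp-to-edge border.

    Returns (values,) or (values, dvalue/dp) with the gradient in voxel units.
    The gradient of the clamped coordinate is taken as zero outside the grid
    (the sampled value is constant there).
    """
    n = np.asarray(vox.shape, dtype=np.float64)
    pc = np.clip(p, 0.0, n - 1.0)
    f = np.floor(pc)
    # keep the base cell inside [0, n-2] so f+1 is valid
    f = np.minimum(f, n - 2.0)
    w = pc - f  # fractional weights in [0, 1]
    i = f.astype(np.intp)

    i0, j0, k0 = i[..., 0], i[..., 1], i[..., 2]
    wx, wy, wz = w[..., 0], w[..., 1], w[..., 2]

    c000 = vox[i0, j0, k0]
    c100 = vox[i0 + 1, j0, k0]
    c010 = vox[i0, j0 + 1, k0]
    c110 = vox[i0 + 1, j0 + 1, k0]
    c001 = vox[i0, j0, k0 + 1]
    c101 = vox[i0 + 1, j0, k0 + 1]
    c011 = vox[i0, j0 + 1, k0 + 1]
    c111 = vox[i0 + 1, j0 + 1, k0 + 1]

    # interpolate along z, then y, then x
    c00 = c000 + (c001 - c000) * wz
    c01 = c010 + (c011 - c010) * wz
    c10 = c100 + (c101 - c100) * wz
    c11 = c110 + (c111 - c110) * wz
    c0 = c00 + (c01 - c00) * wy
    c1 = c10 + (c11 - c10) * wy
    val = c0 + (c1 - c0) * wx

    if not want_grad:
        return (val,)

    dval_dx = c1 - c0
    d00 = c01 - c00
    d10 = c11 - c10
    dval_dy = d00 + (d10 - d00) * wx
    e00 = c001 - c000
    e01 = c011 - c010
    e10 = c101 - c100
    e11 = c111 - c110
    e0 = e00 + (e01 - e00) * wy
    e1 = e10 + (e11 - e10) * wy
    dval_dz = e0 + (e1 - e0) * wx

    grad = np.stack([dval_dx, dval_dy, dval_dz], axis=-1)
    # clamp: zero gradient where the raw coordinate left the grid
    outside = (p < 0.0) | (p > n - 1.0)
    grad[outside] = 0.0
    return val, grad


def trilinear_sample(volume, p) -> np.ndarray:
    """Sample a volume at continuous voxel-index positions.

    Exact at integer indices; trilinear blend of the 8 surrounding voxels
    elsewhere; clamp-to-edge outside the grid.
    """
    vox = volume.voxels if isinstance(volume, ImageVolume) else np.asarray(volume, dtype=np.float64)
    p, squeeze = _as_points(p)
    (val,) = _trilinear(vox, p, want_grad=False)
    return val[0] if squeeze else val


def trilinear_sample_grad(volume, p):
    """Like :func:`trilinear_sample` but also returns d(value)/d(position).

    The spatial gradient is piecewise constant per cell (the analytic
    derivative of the trilinear blend) and zero outside the clamped border.
    """
    vox = volume.voxels if isinstance(volume, ImageVolume) else np.asarray(volume, dtype=np.float64)
    p, squeeze = _as_points(p)
    val, grad = _trilinear(vox, p, want_grad=True)
    if squeeze:
        return val[0], grad[0]
    return val, grad


def warp_image(moving: ImageVolume, mapped_points: np.ndarray) -> ImageVolume:
    """Backward-warp ``moving`` onto the fixed grid.

    ``mapped_points`` holds, for every fixed-grid voxel center z, the
    continuous voxel-index location map(z) in the moving image; the output
    voxel at z is ``trilinear_sample(moving, map(z))``.

    Accepts either a dense (n0, n1, n2, 3) array of mapped coordinates or a
    callable taking an (N, 3) array of grid points.
    """
    shape = moving.shape
    if callable(mapped_points):
        grid = voxel_grid_points(shape)
        mapped = np.asarray(mapped_points(grid), dtype=np.float64).reshape(*shape, 3)
    else:
        mapped = np.asarray(mapped_points, dtype=np.float64)
        if mapped.shape != (*shape, 3):
            raise ValueError(
                f"mapped points shape {mapped.shape} incompatible with grid {shape}"
            )
    if not np.all(np.isfinite(mapped)):
        bad = np.argwhere(~np.all(np.isfinite(mapped), axis=-1))[:1]
        raise ValueError(f"warp map produced non-finite coordinates, e.g. at voxel {bad}")
    flat = mapped.reshape(-1, 3)
    vals = trilinear_sample(moving, flat).reshape(shape)
    return ImageVolume(vals, moving.spacing.copy(), moving.origin.copy())


def voxel_grid_points(shape) -> np.ndarray:
    """All voxel centers of a grid as an (N, 3) array of 0-based indices."""
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=-1)
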