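"""Evaluation suite: TRE, MAE, PSNR, SSIM, NMSE, NCC, Dice, folding ratio.

Conventions (each parameterized and recorded in the report):

* TRE maps the fixed-phase landmarks through the fitted forward map and
  measures the Euclidean mm distance to the moving-phase landmarks, with
  anisotropic spacing applied per axis.
* MAE is reported in native intensity units (HU), never on normalized
  intensities.
* PSNR uses a caller-supplied peak (by default the maximum of the reference
  frame); identical images return ``inf``.
* SSIM is computed in 3D with a Gaussian window (sigma = 1.5) and
  stabilizers proportional to the data range.
* NMSE normalizes the squared error by the reference frame's energy.
* The negative-Jacobian-determinant ratio estimates the Jacobian of
  (identity + displacement) by central differences at interior voxels and
  reports the percentage with det <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.metrics import structural_similarity

from .core import ImageVolume, LandmarkSet, RegionMask, warp_image
from .integration import DenseDVF

__all__ = [
    "MetricsReport",
    "tre",
    "mae",
    "psnr",
    "ssim",
    "nmse",
    "ncc_metric",
    "dice",
    "neg_jacdet_ratio",
    "warp_mask",
]


@dataclass
class MetricsReport:
    """Flat collection of named metric values with units, JSON/CSV-exportable."""

    region: str = "all"
    values: dict = dc_field(default_factory=dict)  # name -> (value, unit)
    per_landmark_mm: np.ndarray | None = None

    def add(self, name: str, value: float, unit: str = "") -> None:
        self.values[name] = (float(value), unit)

    def __getitem__(self, name: str) -> float:
        return self.values[name][0]

    def to_dict(self) -> dict:
        out = {"region": self.region}
        for name, (value, unit) in self.values.items():
            out[name] = value
            if unit:
                out[f"{name}_unit"] = unit
        if self.per_landmark_mm is not None:
            out["per_landmark_mm"] = [float(v) for v in self.per_landmark_mm]
        return out

    def to_json(self, path) -> None:
        import json

        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path, case: str = "") -> None:
        from pathlib import Path

        lines = ["case,region,metric,value,unit"]
        for name, (value, unit) in self.values.items():
            lines.append(f"{case},{self.region},{name},{value!r},{unit}")
        Path(path).write_text("\n".join(lines) + "\n")


def _check_grids(a: ImageVolume, b: ImageVolume) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grids differ: {a.shape} vs {b.shape}")


def tre(
    fixed_lms: LandmarkSet,
    moving_lms: LandmarkSet,
    mapped_points: np.ndarray,
    spacing,
):
    """Target registration error in mm.

    ``mapped_points`` are the fixed landmarks already sent through the
    fixed-to-moving map (continuous voxel indices). Per-axis voxel offsets to
    the paired moving landmarks are converted to mm through ``spacing``.

    Returns (per_landmark_mm, mean, sd).
    """
    if len(fixed_lms) != len(moving_lms):
        raise ValueError("landmark sets must be paired (equal cardinality)")
    mapped = np.atleast_2d(np.asarray(mapped_points, dtype=np.float64))
    if mapped.shape != moving_lms.points.shape:
        raise ValueError("mapped points shape must match the landmark sets")
    spacing = np.asarray(spacing, dtype=np.float64).reshape(3)
    delta_mm = (mapped - moving_lms.points) * spacing
    d = np.linalg.norm(delta_mm, axis=1)
    return d, float(d.mean()), float(d.std())


def mae(a: ImageVolume, b: ImageVolume, mask: RegionMask | None = None) -> float:
    """Mean absolute intensity difference (HU) over the mask or whole grid."""
    _check_grids(a, b)
    diff = np.abs(a.voxels - b.voxels)
    if mask is not None:
        mask.check_aligned(a)
        if not mask.voxels.any():
            raise ValueError("empty mask")
        diff = diff[mask.voxels]
    return float(diff.mean())


def psnr(reference: ImageVolume, test: ImageVolume, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(peak^2 / MSE).

    ``peak`` defaults to the reference frame's maximum intensity. Identical
    images return ``inf``.
    """
    _check_grids(reference, test)
    if peak is None:
        peak = float(reference.voxels.max())
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((reference.voxels - test.voxels) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / mse))


def ssim(
    a: ImageVolume,
    b: ImageVolume,
    sigma: float = 1.5,
    data_range: float | None = None,
) -> float:
    """3D structural similarity with a Gaussian window (sigma = 1.5)."""
    _check_grids(a, b)
    if data_range is None:
        data_range = float(a.voxels.max() - a.voxels.min())
        if data_range == 0.0:
            return 1.0 if np.array_equal(a.voxels, b.voxels) else 0.0
    return float(
        structural_similarity(
            a.voxels,
            b.voxels,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


def nmse(reference: ImageVolume, test: ImageVolume) -> float:
    """Normalized MSE: sum((ref - test)^2) / sum(ref^2)."""
    _check_grids(reference, test)
    denom = float(np.sum(reference.voxels**2))
    if denom == 0.0:
        raise ValueError("reference frame has zero energy")
    return float(np.sum((reference.voxels - test.voxels) ** 2) / denom)


def ncc_metric(a: ImageVolume, b: ImageVolume, mask: RegionMask | None = None) -> float:
    """Zero-normalized cross-correlation of two volumes in [-1, 1]."""
    from .objectives import ncc as _ncc

    _check_grids(a, b)
    av, bv = a.voxels.ravel(), b.voxels.ravel()
    if mask is not None:
        mask.check_aligned(a)
        sel = mask.voxels.ravel()
        av, bv = av[sel], bv[sel]
    return _ncc(av, bv)


def dice(a: RegionMask, b: RegionMask) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks give 1.0."""
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    na, nb = int(a.voxels.sum()), int(b.voxels.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def neg_jacdet_ratio(dvf: DenseDVF, spacing=None) -> float:
    """Percentage of interior voxels with Jacobian determinant <= 0.

    The Jacobian of (identity + displacement) is estimated by central
    differences in voxel units; only interior voxels (one-voxel margin) are
    counted. The ratio is invariant to adding a constant displacement. A
    spacing argument is accepted for interface symmetry but does not change
    the sign of the determinant (positive per-axis scaling).
    """
    shape = dvf.grid_shape
    if min(shape) < 3:
        raise ValueError("grid must be at least 3 voxels along each axis")
    mapped = dvf.mapped_points()
    J = np.empty((*shape, 3, 3))
    for axis in range(3):
        J[..., axis] = np.gradient(mapped, axis=axis)
    interior = J[1:-1, 1:-1, 1:-1]
    det = np.linalg.det(interior)
    return float(100.0 * np.mean(det <= 0.0))


def warp_mask(mask: RegionMask, mapped_points: np.ndarray) -> RegionMask:
    """Backward-warp a binary mask: trilinear on the real-valued indicator,
    thresholded at 0.5."""
    vol = ImageVolume(mask.voxels.astype(np.float64))
    warped = warp_image(vol, mapped_points)
    return RegionMask(warped.voxels >= 0.5)


def evaluate_pair(
    reference: ImageVolume,
    test: ImageVolume,
    mask: RegionMask | None = None,
    region: str = "all",
) -> MetricsReport:
    """Bundle the image-similarity metrics for one frame pair."""
    rep = MetricsReport(region=region)
    rep.add("mae", mae(reference, test, mask), "HU")
    rep.add("psnr", psnr(reference, test), "dB")
    rep.add("ncc", ncc_metric(reference, test, mask))
    rep.add("ssim", ssim(reference, test))
    rep.add("nmse", nmse(reference, test))
    return rep
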