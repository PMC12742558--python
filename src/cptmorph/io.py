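"""Readers and writers: NIfTI / MetaImage volumes, DIR-Lab landmark text,
DVF export, masks.

Axis convention: the in-memory voxel array is indexed (i, j, k) in the same
order as the spacing vector. NIfTI files are handled with nibabel (the data
array is already (i, j, k)); MetaImage with SimpleITK, transposing between
ITK's (z, y, x) array order and ours.

The DVF export stores displacements in mm in the fixed image's voxel-axis
frame (not world-rotated), as a 4D NIfTI with three components per voxel; a
JSON sidecar states the convention, time span and step count.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import ImageVolume, LandmarkSet, RegionMask
from .integration import DenseDVF

__all__ = [
    "VolumeIOError",
    "LandmarkParseError",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_landmarks",
    "write_landmarks",
    "write_dvf",
    "read_dvf",
]

_NIFTI_EXTS = (".nii", ".nii.gz")
_META_EXTS = (".mha", ".mhd")


class VolumeIOError(IOError):
    """A volume file could not be read or written."""


class LandmarkParseError(ValueError):
    """A landmark text file contains a malformed line."""


def _ext(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_volume(path) -> ImageVolume:
    """Read a 3D volume (.nii, .nii.gz, .mha, .mhd) with spacing and origin."""
    path = Path(path)
    ext = _ext(path)
    if ext in _NIFTI_EXTS:
        import nibabel as nib

        try:
            img = nib.load(str(path))
            data = np.asarray(img.dataobj, dtype=np.float64)
            zooms = img.header.get_zooms()[:3]
            origin = np.asarray(img.affine[:3, 3], dtype=np.float64)
        except Exception as exc:  # malformed header, truncated file, ...
            raise VolumeIOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    elif ext in _META_EXTS:
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img).T.astype(np.float64)
            zooms = img.GetSpacing()
            origin = np.asarray(img.GetOrigin(), dtype=np.float64)
        except Exception as exc:
            raise VolumeIOError(f"cannot read MetaImage volume {path}: {exc}") from exc
    else:
        raise VolumeIOError(f"unrecognized volume extension {ext!r} for {path}")
    if data.ndim != 3:
        raise VolumeIOError(f"{path} is not a 3D volume (ndim={data.ndim})")
    return ImageVolume(data, np.asarray(zooms, dtype=np.float64), origin)


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume; format chosen by extension. Spacing/origin preserved."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ext = _ext(path)
    if ext in _NIFTI_EXTS:
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(vol.spacing)
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.voxels, affine), str(path))
    elif ext in _META_EXTS:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.T))
        img.SetSpacing(tuple(map(float, vol.spacing)))
        img.SetOrigin(tuple(map(float, vol.origin)))
        sitk.WriteImage(img, str(path))
    else:
        raise VolumeIOError(f"unrecognized volume extension {ext!r} for {path}")


def read_mask(path) -> RegionMask:
    """Read a binary region mask (any volume format; threshold at 0.5)."""
    return RegionMask(read_volume(path).voxels >= 0.5)


def read_landmarks(path, index_base: int = 0, frame_label: str = "") -> LandmarkSet:
    """Read whitespace-separated voxel-index triples, one landmark per line.

    Blank lines are ignored. Files declared 1-based (the DIR-Lab convention,
    ``index_base=1``) are converted to the 0-based internal convention.
    """
    if index_base not in (0, 1):
        raise ValueError("index_base must be 0 or 1")
    path = Path(path)
    points = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) != 3:
            raise LandmarkParseError(
                f"{path}:{lineno}: expected 3 values, got {len(tokens)}"
            )
        try:
            points.append([float(tok) for tok in tokens])
        except ValueError as exc:
            raise LandmarkParseError(f"{path}:{lineno}: non-numeric token") from exc
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3) - index_base
    return LandmarkSet(pts, frame_label=frame_label or path.stem)


def write_landmarks(lms: LandmarkSet, path, index_base: int = 0) -> None:
    """Write landmarks as whitespace-separated triples (DIR-Lab dialect)."""
    if index_base not in (0, 1):
        raise ValueError("index_base must be 0 or 1")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pts = lms.points + index_base
    path.write_text("\n".join(f"{p[0]:.4f}\t{p[1]:.4f}\t{p[2]:.4f}" for p in pts) + "\n")


def write_dvf(dvf: DenseDVF, reference: ImageVolume, path) -> None:
    """Export a displacement field as a 4D NIfTI in mm, with a JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vec_mm = dvf.vectors * reference.spacing  # voxel units -> mm per axis
    affine = np.eye(4)
    affine[:3, :3] = np.diag(reference.spacing)
    affine[:3, 3] = reference.origin
    nib.save(nib.Nifti1Image(vec_mm, affine), str(path))
    sidecar = {
        "units": "mm",
        "frame": "fixed-image voxel axes (not world-rotated)",
        "t0": dvf.t0,
        "t1": dvf.t1,
        "steps_T": dvf.steps_T,
    }
    Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_dvf(path, reference: ImageVolume) -> DenseDVF:
    """Read a DVF exported by :func:`write_dvf` back into voxel units."""
    import nibabel as nib

    path = Path(path)
    try:
        img = nib.load(str(path))
        vec_mm = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:
        raise VolumeIOError(f"cannot read DVF {path}: {exc}") from exc
    meta_path = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return DenseDVF(
        vec_mm / reference.spacing,
        t0=float(meta.get("t0", 0.0)),
        t1=float(meta.get("t1", 1.0)),
        steps_T=int(meta.get("steps_T", 1)),
    )
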