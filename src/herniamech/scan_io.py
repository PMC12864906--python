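"""Loading, saving and resampling of CT volumes and masks.

Accepts NIfTI files (``.nii`` / ``.nii.gz``) and DICOM series directories.
Every volume is reoriented to the canonical ``x`` (L-R), ``y`` (P-A),
``z`` (I-S) axis order on load; DICOM slices are ordered by their spatial
position along the slice normal, never by file name, and a non-uniform
slice increment is a hard geometry error (a missing or duplicated slice
silently corrupts the displacement field downstream).
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

from .core import BinaryMask, GridRaster, LabelMap, Phase, ScanVolume, replace


class ScanFormatError(ValueError):
    """The file or series could not be read as a CT volume."""


class ScanGeometryError(ValueError):
    """The series geometry is inconsistent (e.g. a missing slice)."""


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_scan(path: str | os.PathLike, phase: Phase | str = Phase.REST) -> ScanVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path:
        A ``.nii``/``.nii.gz`` file or a directory containing one DICOM
        series.
    phase:
        Acquisition phase tag (``rest`` or ``valsalva``).
    """
    path = Path(path)
    phase = Phase(phase)
    if path.is_dir():
        return _load_dicom_series(path, phase)
    if path.name.endswith((".nii", ".nii.gz")):
        return _load_nifti(path, phase)
    raise ScanFormatError(f"unsupported scan input: {path}")


def _load_nifti(path: Path, phase: Phase) -> ScanVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise ScanFormatError(f"could not read NIfTI file {path}: {exc}") from exc
    # Reorient to RAS so the array matches the canonical axis order.
    ornt = nib.orientations.io_orientation(img.affine)
    data = nib.orientations.apply_orientation(np.asanyarray(img.dataobj), ornt)
    aff = img.affine @ nib.orientations.inv_ornt_aff(ornt, img.shape)
    rot = aff[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    # Oblique acquisitions are out of scope: require an axis-aligned frame.
    if np.max(np.abs(rot - np.diag(spacing))) > 1e-3 * spacing.max():
        raise ScanGeometryError(f"{path}: affine is not axis-aligned after reorientation")
    return ScanVolume(
        voxels=np.asarray(data, dtype=np.float32),
        spacing=spacing,
        origin=aff[:3, 3],
        phase=phase,
    )


def _load_dicom_series(directory: Path, phase: Phase) -> ScanVolume:
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ScanFormatError(f"no readable DICOM images in {directory}")

    normal = _slice_normal(datasets[0])
    datasets.sort(key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)))
    positions = np.array(
        [np.dot(np.asarray(ds.ImagePositionPatient, float), normal) for ds in datasets]
    )
    if len(datasets) < 2:
        raise ScanFormatError(f"series in {directory} has fewer than 2 slices")
    gaps = np.diff(positions)
    if np.any(gaps <= 0):
        raise ScanGeometryError(f"{directory}: duplicate slice positions in series")
    if np.max(np.abs(gaps - gaps[0])) > 0.01 * gaps[0] + 1e-3:
        bad = int(np.argmax(np.abs(gaps - gaps[0])))
        raise ScanGeometryError(
            f"{directory}: non-uniform slice increment (missing slice?) between "
            f"positions {positions[bad]:.2f} and {positions[bad + 1]:.2f} mm "
            f"(gap {gaps[bad]:.2f} mm vs expected {gaps[0]:.2f} mm)"
        )

    first = datasets[0]
    row_spacing, col_spacing = (float(v) for v in first.PixelSpacing)
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    # pixel_array is (row, col) = (y, x); stack to (x, y, z).
    stack = np.stack(
        [ds.pixel_array.astype(np.float32).T for ds in datasets], axis=-1
    )
    hu = stack * slope + intercept
    origin = np.asarray(first.ImagePositionPatient, dtype=float)
    return ScanVolume(
        voxels=hu,
        spacing=np.array([col_spacing, row_spacing, float(gaps[0])]),
        origin=origin,
        phase=phase,
    )


def _slice_normal(ds) -> np.ndarray:
    iop = np.asarray(getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    return np.cross(iop[:3], iop[3:])


# ---------------------------------------------------------------------------
# saving
# ---------------------------------------------------------------------------

def save_nifti(raster: GridRaster, path: str | os.PathLike) -> None:
    """Write a raster (scan, mask, label map or vector field) as NIfTI."""
    data = raster.voxels
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, raster.affine())
    img.header.set_zooms(tuple(raster.spacing) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_isotropic(vol: GridRaster, target_spacing: float = 1.0) -> GridRaster:
    """Resample a raster onto an isotropic grid covering the same extent.

    HU volumes are interpolated linearly, masks and label maps with nearest
    neighbours; world coordinates of the content are preserved (the origin
    is unchanged and the new lattice spans the same voxel-centre extent).
    """
    if target_spacing <= 0:
        raise ValueError(f"target_spacing must be positive, got {target_spacing}")
    lo, hi = vol.world_extent()
    new_shape = np.maximum(np.floor((hi - lo) / target_spacing).astype(int) + 1, 2)
    new_spacing = np.full(3, float(target_spacing))

    # Map output voxel indices to fractional input indices.
    grids = np.meshgrid(*[np.arange(n) for n in new_shape], indexing="ij")
    world = lo + np.stack(grids, axis=-1) * new_spacing
    frac = (world - vol.origin) / vol.spacing
    coords = np.moveaxis(frac, -1, 0)

    is_scalar_hu = isinstance(vol, ScanVolume)
    order = 1 if is_scalar_hu else 0
    if is_scalar_hu:
        src = vol.voxels.astype(np.float32)
    elif vol.voxels.dtype == bool:
        src = vol.voxels.astype(np.uint8)
    else:
        src = vol.voxels
    out = ndimage.map_coordinates(src, coords, order=order, mode="nearest")
    return replace(vol, voxels=out, spacing=new_spacing, origin=lo)
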