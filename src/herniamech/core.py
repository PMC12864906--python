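"""Core grid-attached data containers shared across the pipeline.

All rasters use a single convention: the voxel array is indexed ``(i, j, k)``
along the patient axes ``x`` (left-right), ``y`` (posterior-anterior) and
``z`` (inferior-superior), indices are 0-based, and the world coordinate of
voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing`` in millimetres.
Volumes loaded from disk are reoriented into this frame once, on load, so no
downstream code ever branches on orientation.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np


class Phase(str, enum.Enum):
    """Acquisition phase of a scan: quiet expiration or forced Valsalva."""

    REST = "rest"
    VALSALVA = "valsalva"


class MaskProvenance(str, enum.Enum):
    BODY_OUTLINE = "body_outline"
    LABEL_CLASS = "label_class"
    WARPED = "warped"


#: Integer classes of a segmentation label map.
LABEL_CLASSES: Mapping[int, str] = {
    0: "background",
    1: "abdominal_cavity",
    2: "rectus_muscle",
    3: "lateral_muscle_1",
    4: "lateral_muscle_2",
    5: "lateral_muscle_3",
    6: "hernia_sac",
}

#: Fixed anatomical axis order every raster is reoriented to on load.
CANONICAL_AXIS_CODES = "RAS"


def _as_vec3(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 components, got {arr.size}")
    return arr


@dataclass
class GridRaster:
    """A 3D raster with world-coordinate metadata (mm).

    Base class for scans, masks, label maps and vector fields; subclasses
    constrain the dtype and add semantics.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axis_codes: str = CANONICAL_AXIS_CODES

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.voxels.ndim < 3 or any(s < 2 for s in self.voxels.shape[:3]):
            raise ValueError(
                f"voxel array must be 3D with each axis >= 2, got shape {self.voxels.shape}"
            )

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape[:3])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx) -> np.ndarray:
        """World coordinates (mm) of 0-based voxel indices, shape (..., 3)."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, xyz) -> np.ndarray:
        """Continuous voxel indices of world points, shape (..., 3)."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) world corners of the voxel-centre lattice."""
        hi = self.index_to_world(np.array(self.shape) - 1)
        return self.origin.copy(), hi

    def same_grid(self, other: "GridRaster", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world affine (diagonal by construction)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class ScanVolume(GridRaster):
    """A CT volume in Hounsfield units on a regular grid."""

    phase: Phase = Phase.REST

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.voxels.ndim != 3:
            raise ValueError("ScanVolume voxels must be a 3D scalar array")
        self.voxels = self.voxels.astype(np.float32, copy=False)
        self.phase = Phase(self.phase)


@dataclass
class BinaryMask(GridRaster):
    """A boolean raster (body outline, label class or warped mask)."""

    provenance: MaskProvenance = MaskProvenance.BODY_OUTLINE

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.voxels.ndim != 3:
            raise ValueError("BinaryMask voxels must be a 3D array")
        self.voxels = self.voxels.astype(bool, copy=False)
        self.provenance = MaskProvenance(self.provenance)

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume_mm3

    def centroid_world(self) -> np.ndarray:
        idx = np.argwhere(self.voxels)
        if idx.size == 0:
            raise ValueError("empty mask has no centroid")
        return self.index_to_world(idx.mean(axis=0))


@dataclass
class LabelMap(GridRaster):
    """Integer-class raster: cavity, muscle layers and hernia sac."""

    class_table: Mapping[int, str] = field(default_factory=lambda: dict(LABEL_CLASSES))

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.voxels.ndim != 3:
            raise ValueError("LabelMap voxels must be a 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("LabelMap voxels must be integer-typed")
        present = set(np.unique(self.voxels).tolist())
        unknown = present - set(int(k) for k in self.class_table)
        if unknown:
            raise ValueError(f"label map contains ids not in the class table: {sorted(unknown)}")

    def class_mask(self, class_id: int) -> BinaryMask:
        if class_id not in self.class_table:
            raise ValueError(f"unknown class id {class_id}")
        return BinaryMask(
            voxels=self.voxels == class_id,
            spacing=self.spacing,
            origin=self.origin,
            axis_codes=self.axis_codes,
            provenance=MaskProvenance.LABEL_CLASS,
        )


def replace(obj, **changes):
    """dataclasses.replace passthrough, re-exported for convenience."""
    return dataclasses.replace(obj, **changes)
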