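"""Body-surface meshes, displacement mapping and the unstable-wall statistic.

The clinical quantity of interest is the *unstable abdominal wall*: the
body-surface area whose displacement between rest and Valsalva exceeds a
threshold (15 mm by default, user-settable). Surfaces are extracted from
the body masks by marching cubes, the displacement magnitude is mapped
onto each vertex, and the statistic is the summed area of triangles whose
mean vertex displacement exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import trimesh
from skimage import measure

from .core import BinaryMask, Phase
from .registration import (
    DisplacementField,
    invert_field,
    sample_field_clamped,
)


@dataclass
class SurfaceMesh:
    """Triangle mesh in world coordinates with named per-vertex channels."""

    vertices: np.ndarray  # (n, 3) mm
    triangles: np.ndarray  # (m, 3) int
    scalars: dict = dc_field(default_factory=dict)
    phase: Phase = Phase.REST
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.phase = Phase(self.phase)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle indices exceed vertex count")
        for name, vals in self.scalars.items():
            if len(np.asarray(vals)) != len(self.vertices):
                raise ValueError(f"channel {name!r} length != vertex count")

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area_mm2(self) -> float:
        return float(self.triangle_areas().sum())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.triangles, process=False)

    def export_ply(self, path) -> None:
        tm = self.to_trimesh()
        if "colour" in self.scalars:
            rgba = np.hstack(
                [
                    np.clip(self.scalars["colour"] * 255, 0, 255).astype(np.uint8),
                    np.full((len(self.vertices), 1), 255, dtype=np.uint8),
                ]
            )
            tm.visual.vertex_colors = rgba
        tm.export(str(path))


@dataclass
class InstabilityResult:
    unstable_area_cm2: float
    total_area_cm2: float
    max_displacement_mm: float
    threshold_mm: float
    surface_phase: Phase

    def __post_init__(self) -> None:
        if self.threshold_mm <= 0:
            raise ValueError("threshold_mm must be positive")
        if not 0 <= self.unstable_area_cm2 <= self.total_area_cm2 * (1 + 1e-12):
            raise ValueError("unstable area must lie within [0, total area]")

    def to_dict(self) -> dict:
        return {
            "unstable_area_cm2": self.unstable_area_cm2,
            "total_area_cm2": self.total_area_cm2,
            "max_displacement_mm": self.max_displacement_mm,
            "threshold_mm": self.threshold_mm,
            "surface_phase": self.surface_phase.value,
        }


# ---------------------------------------------------------------------------
# surface extraction and mapping
# ---------------------------------------------------------------------------

def extract_surface(
    mask: BinaryMask, phase: Phase | str | None = None, smooth_voxels: float = 1.0
) -> SurfaceMesh:
    """Closed triangle mesh of the mask isosurface (marching cubes).

    The binary raster is smoothed with a one-voxel Gaussian before
    isosurfacing: marching cubes on raw 0/1 data produces a staircase
    whose area overestimates the true surface by several percent, while
    the smoothed 0.5-level surface recovers smooth-shape areas to well
    under 1%. The mask is padded so surfaces touching the volume border
    still close; only the largest connected surface component is kept and
    degenerate triangles are dropped.
    """
    from scipy import ndimage as _ndi

    if not mask.voxels.any():
        raise ValueError("cannot extract a surface from an empty mask")
    pad = max(int(np.ceil(3 * smooth_voxels)), 1)
    padded = np.pad(mask.voxels, pad, mode="constant", constant_values=False).astype(np.float32)
    if smooth_voxels > 0:
        padded = _ndi.gaussian_filter(padded, smooth_voxels)
    # tiny masks smooth below 0.5 everywhere; drop the level to keep a surface
    level = 0.5 if padded.max() > 0.6 else 0.5 * float(padded.max())
    verts, faces, _, _ = measure.marching_cubes(padded, level=level, spacing=tuple(mask.spacing))
    verts = verts + (mask.origin - pad * mask.spacing)

    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda p: p.area)
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()

    return SurfaceMesh(
        vertices=np.asarray(tm.vertices),
        triangles=np.asarray(tm.faces),
        phase=Phase(phase) if phase is not None else Phase.REST,
    )


def map_displacement(mesh: SurfaceMesh, field: DisplacementField) -> SurfaceMesh:
    """Attach the per-vertex displacement magnitude channel.

    Rest-phase vertices sample the forward field directly. Valsalva-phase
    vertices sample the inverted field, so each Valsalva surface point
    carries the magnitude of the vector connecting it to its rest-position
    counterpart — both surfaces then express the same deformation relative
    to the rest state. Vertices outside the field extent are clamped to
    the nearest voxel; the count is recorded in ``meta``.
    """
    if mesh.phase is Phase.VALSALVA:
        vecs, clamped = sample_field_clamped(invert_field(field), mesh.vertices)
    else:
        vecs, clamped = sample_field_clamped(field, mesh.vertices)
    mags = np.linalg.norm(vecs, axis=1)
    scalars = dict(mesh.scalars)
    scalars["displacement_mm"] = mags
    meta = dict(mesh.meta)
    meta["clamped_vertices"] = int(clamped)
    return SurfaceMesh(mesh.vertices, mesh.triangles, scalars, mesh.phase, meta)


def map_scalar_volume(
    mesh: SurfaceMesh, values: np.ndarray, like, channel: str
) -> SurfaceMesh:
    """Attach a channel by trilinear sampling of a scalar volume at vertices."""
    from scipy import ndimage

    idx = like.world_to_index(mesh.vertices)
    idx = np.clip(idx, 0, np.asarray(values.shape) - 1)
    sampled = ndimage.map_coordinates(values.astype(float), idx.T, order=1, mode="nearest")
    scalars = dict(mesh.scalars)
    scalars[channel] = sampled
    return SurfaceMesh(mesh.vertices, mesh.triangles, scalars, mesh.phase, dict(mesh.meta))


# ---------------------------------------------------------------------------
# the instability statistic
# ---------------------------------------------------------------------------

def unstable_area(mesh: SurfaceMesh, threshold_mm: float = 15.0) -> InstabilityResult:
    """Area (cm²) of the surface displaced by more than the threshold.

    A triangle counts as unstable when the mean of its three vertex
    displacements exceeds ``threshold_mm`` — unbiased at the boundary
    compared with any-vertex or all-vertices rules.
    """
    if "displacement_mm" not in mesh.scalars:
        raise ValueError("mesh has no 'displacement_mm' channel; run map_displacement first")
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    disp = np.asarray(mesh.scalars["displacement_mm"], dtype=float)
    areas = mesh.triangle_areas()
    tri_disp = disp[mesh.triangles].mean(axis=1)
    unstable = float(areas[tri_disp > threshold_mm].sum())
    return InstabilityResult(
        unstable_area_cm2=unstable / 100.0,
        total_area_cm2=float(areas.sum()) / 100.0,
        max_displacement_mm=float(disp.max()) if disp.size else 0.0,
        threshold_mm=float(threshold_mm),
        surface_phase=mesh.phase,
    )


def colourize(mesh: SurfaceMesh, threshold_mm: float = 15.0) -> np.ndarray:
    """Two-regime vertex colours for the displacement channel.

    Below the threshold the ramp runs blue → cyan over [0, τ); at and
    above it runs red → yellow → white over [τ, max]. The deliberate
    discontinuity at τ makes the unstable region pop visually. The (n, 3)
    RGB array is returned and stored as the ``colour`` channel.
    """
    if "displacement_mm" not in mesh.scalars:
        raise ValueError("mesh has no 'displacement_mm' channel; run map_displacement first")
    d = np.asarray(mesh.scalars["displacement_mm"], dtype=float)
    colours = np.zeros((len(d), 3))

    below = d < threshold_mm
    frac_b = np.clip(d / threshold_mm, 0.0, 1.0)
    colours[below] = np.column_stack(
        [np.zeros_like(frac_b), frac_b, np.ones_like(frac_b)]
    )[below]  # blue (0,0,1) -> cyan (0,1,1)

    above = ~below
    if above.any():
        dmax = float(d.max())
        span = max(dmax - threshold_mm, 1e-12)
        frac_a = np.clip((d - threshold_mm) / span, 0.0, 1.0)
        # red (1,0,0) -> yellow (1,1,0) -> white (1,1,1)
        g = np.clip(2.0 * frac_a, 0.0, 1.0)
        b = np.clip(2.0 * frac_a - 1.0, 0.0, 1.0)
        colours[above] = np.column_stack([np.ones_like(frac_a), g, b])[above]

    mesh.scalars["colour"] = colours
    return colours
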