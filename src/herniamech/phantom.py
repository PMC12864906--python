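"""Synthetic torso phantom with analytic deformation ground truth.

Patient CT data cannot be shared, so every pipeline stage is validated on
a phantom: an ellipsoidal torso with a muscle shell, an abdominal cavity,
an optional hernia sac protruding through a wall gap, and a patient-table
slab. The Valsalva state is the rest state pushed anteriorly by a smooth
Gaussian bulge

    u(p) = A · exp(−Σᵢ (pᵢ − cᵢ)² / 2σᵢ²) · ŷ        (ŷ = anterior)

whose displacement, gradient and Green-Lagrange strain all have closed
forms, providing an exact oracle for registration, strain, surface and
landmark code. The amplitude/width combination must satisfy
``A·exp(−1/2)/σ_y < 1`` so the map ``x ↦ x + u(x)`` stays diffeomorphic.

The Valsalva volume is produced by backward warping through the exact
inverse deformation (fixed-point iteration to 0.01 mm), so the rest and
Valsalva rasters correspond point-to-point through ``u`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import trimesh
from scipy import ndimage

from .core import BinaryMask, LabelMap, LABEL_CLASSES, MaskProvenance, Phase, ScanVolume
from .landmark_validation import LandmarkSet
from .registration import DisplacementField
from .strain_mechanics import green_lagrange

_AIR_HU = -1000.0


@dataclass
class HerniaSpec:
    """Wall gap plus protruding sac, labelled as the hernia class."""

    gap_half_width_mm: float = 30.0
    sac_radius_mm: float = 40.0


@dataclass
class PhantomSpec:
    """Geometry, deformation, imaging and electrode parameters."""

    semi_axes_mm: tuple[float, float, float] = (140.0, 100.0, 120.0)
    wall_thickness_mm: float = 15.0
    hernia: HerniaSpec | None = dc_field(default_factory=HerniaSpec)
    bulge_amplitude_mm: float = 25.0
    bulge_centre_mm: tuple[float, float, float] | None = None  # default: anterior pole
    bulge_sigma_mm: tuple[float, float, float] = (80.0, 80.0, 60.0)
    grid_spacing_mm: float = 3.0
    margin_mm: float = 15.0
    include_table: bool = True
    hu_values: dict = dc_field(
        default_factory=lambda: {
            "air": -1000.0,
            "cavity": -10.0,
            "muscle": 55.0,
            "soft_tissue": 40.0,
            "hernia": 30.0,
            "table": 300.0,
        }
    )
    noise_sd_hu: float = 10.0
    electrode_spacing_mm: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes_mm
        if min(a, b, c) <= self.wall_thickness_mm:
            raise ValueError("wall thickness must be smaller than every semi-axis")
        if self.grid_spacing_mm <= 0 or self.margin_mm < 0:
            raise ValueError("grid spacing must be positive and margin non-negative")
        if self.bulge_centre_mm is None:
            self.bulge_centre_mm = (0.0, b, 0.0)
        slope = self.bulge_amplitude_mm * np.exp(-0.5) / self.bulge_sigma_mm[1]
        if slope >= 1.0:
            raise ValueError(
                f"deformation is not diffeomorphic: A·e^(-1/2)/sigma_y = {slope:.2f} >= 1; "
                "reduce the amplitude or widen the bulge"
            )

    # -- closed-form deformation -------------------------------------------
    def displacement(self, points) -> np.ndarray:
        """u(p) in mm at world points, shape (..., 3)."""
        p = np.asarray(points, dtype=float)
        g = self._gaussian(p)
        u = np.zeros(p.shape)
        u[..., 1] = self.bulge_amplitude_mm * g
        return u

    def displacement_gradient(self, points) -> np.ndarray:
        """Closed-form grad u, shape (..., 3, 3): H[i,j] = du_i/dp_j."""
        p = np.asarray(points, dtype=float)
        g = self._gaussian(p)
        c = np.asarray(self.bulge_centre_mm)
        s = np.asarray(self.bulge_sigma_mm)
        dg = -(p - c) / s**2 * g[..., None]  # (..., 3)
        grad = np.zeros(p.shape[:-1] + (3, 3))
        grad[..., 1, :] = self.bulge_amplitude_mm * dg
        return grad

    def strain(self, points) -> np.ndarray:
        """Closed-form Green-Lagrange strain at world points, (..., 3, 3)."""
        return green_lagrange(self.displacement_gradient(points))

    def inverse_displacement(self, points, tol_mm: float = 0.01, max_iterations: int = 100):
        """v with phi^{-1}(y) = y + v(y), by fixed-point iteration on x = y − u(x)."""
        y = np.asarray(points, dtype=float)
        x = y.copy()
        for _ in range(max_iterations):
            x_new = y - self.displacement(x)
            if np.max(np.abs(x_new - x)) < tol_mm:
                x = x_new
                break
            x = x_new
        return x - y

    def _gaussian(self, p: np.ndarray) -> np.ndarray:
        c = np.asarray(self.bulge_centre_mm)
        s = np.asarray(self.bulge_sigma_mm)
        return np.exp(-0.5 * np.sum(((p - c) / s) ** 2, axis=-1))


@dataclass
class PhantomBundle:
    spec: PhantomSpec
    rest_scan: ScanVolume
    valsalva_scan: ScanVolume
    rest_mask: BinaryMask
    valsalva_mask: BinaryMask
    rest_labels: LabelMap
    valsalva_labels: LabelMap
    field: DisplacementField
    landmarks: LandmarkSet
    ground_truth: dict


# ---------------------------------------------------------------------------
# analytic geometry
# ---------------------------------------------------------------------------

def _labels_at(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Class id of the undeformed (rest) phantom at world points."""
    p = np.asarray(points, dtype=float)
    a, b, c = spec.semi_axes_mm
    w = spec.wall_thickness_mm
    x, y, z = p[..., 0], p[..., 1], p[..., 2]

    rho_out = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
    rho_in = (x / (a - w)) ** 2 + (y / (b - w)) ** 2 + (z / (c - w)) ** 2
    outer = rho_out <= 1.0
    inner = rho_in <= 1.0
    shell = outer & ~inner

    labels = np.zeros(p.shape[:-1], dtype=np.uint8)
    labels[inner] = 1  # abdominal cavity

    # muscle shell: rectus anteriorly, three lateral layers by depth below
    # the skin (approximate radial depth; only determinism matters here)
    anterior = (y > 0) & (np.abs(x) < 0.5 * a)
    rectus = shell & anterior
    lateral = shell & ~anterior
    r_out = np.sqrt(np.clip(rho_out, 1e-12, None))
    depth = np.clip((1.0 - r_out) * min(a, b, c) / w, 0.0, 0.999)
    labels[rectus] = 2
    if lateral.any():
        tier = (depth * 3).astype(np.uint8)
        labels[lateral] = (3 + tier)[lateral]

    if spec.hernia is not None:
        hw = spec.hernia.gap_half_width_mm
        rs = spec.hernia.sac_radius_mm
        centre = np.array([0.0, b, 0.0])
        ball = np.sum((p - centre) ** 2, axis=-1) <= rs**2
        gap = (x**2 + z**2) < hw**2
        hernia = ball & ~inner & (((~outer) & (y > 0)) | (shell & gap))
        labels[hernia] = 6
    return labels


def _hu_at(spec: PhantomSpec, labels: np.ndarray) -> np.ndarray:
    hu = spec.hu_values
    lut = np.array(
        [hu["air"], hu["cavity"], hu["muscle"], hu["muscle"], hu["muscle"], hu["muscle"], hu["hernia"]],
        dtype=np.float32,
    )
    return lut[labels]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Build the full phantom bundle, deterministic given the spec seed."""
    spec = spec or PhantomSpec()
    a, b, c = spec.semi_axes_mm
    h = spec.grid_spacing_mm
    m = spec.margin_mm
    sac = spec.hernia.sac_radius_mm if spec.hernia else 0.0
    table_extra = 30.0 if spec.include_table else 0.0

    lo = np.array([-(a + m), -(b + m + table_extra), -(c + m)])
    hi = np.array([a + m, b + spec.bulge_amplitude_mm + sac + m, c + m])
    shape = np.ceil((hi - lo) / h).astype(int) + 1
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    pts = lo + np.stack(grids, axis=-1) * h  # (nx, ny, nz, 3)

    rng = np.random.default_rng(spec.seed)

    # rest phase: evaluate the analytic geometry directly
    rest_label_arr = _labels_at(spec, pts)
    rest_hu = _hu_at(spec, rest_label_arr)

    # valsalva phase: backward warp through the exact inverse deformation
    v = spec.inverse_displacement(pts.reshape(-1, 3)).reshape(pts.shape)
    val_label_arr = _labels_at(spec, pts + v)
    val_hu = _hu_at(spec, val_label_arr)

    # the table is attached to the scanner, not the patient: add it after
    # warping, extending to the posterior image border
    if spec.include_table:
        table = (pts[..., 1] >= lo[1]) & (pts[..., 1] <= -(b + 15.0)) & (np.abs(pts[..., 0]) <= a)
        rest_hu = np.where(table, spec.hu_values["table"], rest_hu)
        val_hu = np.where(table, spec.hu_values["table"], val_hu)

    rest_hu = rest_hu + rng.normal(0.0, spec.noise_sd_hu, rest_hu.shape).astype(np.float32)
    val_hu = val_hu + rng.normal(0.0, spec.noise_sd_hu, val_hu.shape).astype(np.float32)

    spacing = np.full(3, h)
    rest_scan = ScanVolume(rest_hu, spacing, lo, phase=Phase.REST)
    valsalva_scan = ScanVolume(val_hu, spacing, lo, phase=Phase.VALSALVA)
    rest_labels = LabelMap(rest_label_arr, spacing, lo, class_table=dict(LABEL_CLASSES))
    valsalva_labels = LabelMap(val_label_arr, spacing, lo, class_table=dict(LABEL_CLASSES))
    rest_mask = BinaryMask(rest_label_arr > 0, spacing, lo, provenance=MaskProvenance.BODY_OUTLINE)
    valsalva_mask = BinaryMask(val_label_arr > 0, spacing, lo, provenance=MaskProvenance.BODY_OUTLINE)

    field = DisplacementField(
        voxels=spec.displacement(pts),
        spacing=spacing,
        origin=lo,
        provenance={"analytic": True, "bulge_amplitude_mm": spec.bulge_amplitude_mm},
    )

    landmarks = _electrode_grid(spec)
    ground_truth = dict(
        _surface_ground_truth(spec),
        max_landmark_displacement_mm=float(
            np.linalg.norm(landmarks.valsalva - landmarks.rest, axis=1).max()
        ),
    )

    return PhantomBundle(
        spec=spec,
        rest_scan=rest_scan,
        valsalva_scan=valsalva_scan,
        rest_mask=rest_mask,
        valsalva_mask=valsalva_mask,
        rest_labels=rest_labels,
        valsalva_labels=valsalva_labels,
        field=field,
        landmarks=landmarks,
        ground_truth=ground_truth,
    )


def _electrode_grid(spec: PhantomSpec) -> LandmarkSet:
    """Electrodes on the anterior rest surface, transported by the field."""
    a, b, c = spec.semi_axes_mm
    s = spec.electrode_spacing_mm
    xs = np.arange(-a, a + 1e-9, s)
    xs = xs - xs.mean()  # centre the grid
    zs = np.arange(-c, c + 1e-9, s)
    zs = zs - zs.mean()
    ids, rest, val = [], [], []
    for x in xs:
        for z in zs:
            arg = 1.0 - (x / a) ** 2 - (z / c) ** 2
            if arg < 0.15:  # keep electrodes off the grazing lateral edge
                continue
            p = np.array([x, b * np.sqrt(arg), z])
            ids.append(f"E{len(ids):02d}")
            rest.append(p)
            val.append(p + spec.displacement(p))
    return LandmarkSet(
        ids=ids,
        rest=np.array(rest),
        valsalva=np.array(val),
        nominal_grid_spacing_mm=s,
    )


def _surface_ground_truth(spec: PhantomSpec, threshold_mm: float = 15.0) -> dict:
    """Unstable-area ground truth from the closed-form field.

    Evaluated on a finely subdivided analytic ellipsoid (the smooth torso
    surface, without the sac) with the same mean-vertex triangle rule the
    pipeline uses.
    """
    sphere = trimesh.creation.icosphere(subdivisions=4)
    verts = sphere.vertices * np.asarray(spec.semi_axes_mm)
    mags = np.linalg.norm(spec.displacement(verts), axis=1)
    tris = sphere.faces
    cross = np.cross(
        verts[tris[:, 1]] - verts[tris[:, 0]], verts[tris[:, 2]] - verts[tris[:, 0]]
    )
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    tri_disp = mags[tris].mean(axis=1)
    return {
        "unstable_area_cm2": float(areas[tri_disp > threshold_mm].sum() / 100.0),
        "total_area_cm2": float(areas.sum() / 100.0),
        "max_displacement_mm": float(mags.max()),
        "threshold_mm": threshold_mm,
    }


# ---------------------------------------------------------------------------
# controlled corruptions (acquisition failure modes)
# ---------------------------------------------------------------------------

DEGRADE_MODES = ("shift", "scale", "truncate", "foreign_object", "slice_mismatch")


def degrade_pair(
    bundle: PhantomBundle, mode: str, magnitude: float, seed: int = 0
) -> tuple[ScanVolume, ScanVolume]:
    """Apply exactly one acquisition failure mode to the scan pair.

    shift — in-plane translation (mm) of the Valsalva scan content;
    scale — in-plane magnification factor of the Valsalva scan;
    truncate — crop (mm) of the anterior body region from both scans;
    foreign_object — a detached arm-like slab in the Valsalva field of view
    (magnitude > 0 enables it);
    slice_mismatch — remove ``magnitude`` axial slices from the Valsalva scan.

    ``magnitude = 0`` (or scale factor 1) is a no-op and the pair stays
    applicable.
    """
    if mode not in DEGRADE_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}; expected one of {DEGRADE_MODES}")
    rest = ScanVolume(
        bundle.rest_scan.voxels.copy(), bundle.rest_scan.spacing, bundle.rest_scan.origin,
        phase=Phase.REST,
    )
    val = ScanVolume(
        bundle.valsalva_scan.voxels.copy(), bundle.valsalva_scan.spacing,
        bundle.valsalva_scan.origin, phase=Phase.VALSALVA,
    )
    h = val.spacing

    if mode == "shift" and magnitude != 0:
        shifted = ndimage.shift(
            val.voxels, (magnitude / h[0], 0, 0), order=1, mode="constant", cval=_AIR_HU
        )
        val = ScanVolume(shifted, val.spacing, val.origin, phase=Phase.VALSALVA)
    elif mode == "scale" and magnitude not in (0, 1):
        centre = (np.asarray(val.shape) - 1) / 2.0
        matrix = np.diag([1.0 / magnitude, 1.0 / magnitude, 1.0])
        offset = centre - matrix @ centre
        scaled = ndimage.affine_transform(
            val.voxels, matrix, offset=offset, order=1, mode="constant", cval=_AIR_HU
        )
        val = ScanVolume(scaled, val.spacing, val.origin, phase=Phase.VALSALVA)
    elif mode == "truncate" and magnitude != 0:
        body_j = np.nonzero(val.voxels.max(axis=(0, 2)) > -500)[0]
        cut_j = int(body_j.max() - round(magnitude / h[1]))
        rest = ScanVolume(rest.voxels[:, : cut_j + 1, :].copy(), rest.spacing, rest.origin,
                          phase=Phase.REST)
        val = ScanVolume(val.voxels[:, : cut_j + 1, :].copy(), val.spacing, val.origin,
                         phase=Phase.VALSALVA)
    elif mode == "foreign_object" and magnitude != 0:
        arr = val.voxels.copy()
        nx, ny, nz = arr.shape
        arm_x = slice(nx - 3, nx - 1)
        arm_y = slice(ny // 3, ny // 3 + max(int(60 / h[1]), 2))
        arm_z = slice(nz // 4, nz // 4 + max(int(120 / h[2]), 2))
        arr[arm_x, arm_y, arm_z] = 40.0
        val = ScanVolume(arr, val.spacing, val.origin, phase=Phase.VALSALVA)
    elif mode == "slice_mismatch" and magnitude != 0:
        k = max(int(round(magnitude)), 1)
        val = ScanVolume(val.voxels[:, :, :-k].copy(), val.spacing, val.origin,
                         phase=Phase.VALSALVA)
    return rest, val
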