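"""Applicability checks for a rest/Valsalva CT scan pair.

Registration of the two body outlines is only meaningful when both scans
were acquired with identical geometry on the same table position. A scan
pair is screened twice: first on metadata (shape, spacing, origin,
orientation), then on mask content for the classic acquisition failure
modes — truncated field of view, gross in-plane shift or scale mismatch
between the scans, and foreign objects (typically arms) in the field of
view. Failures never raise; they are recorded in a report so a clinical
operator can see every offending check at once.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BinaryMask, GridRaster


class CheckStatus(str, enum.Enum):
    PASS = "pass"
    FAIL = "fail"
    WARN = "warn"


class Applicability(str, enum.Enum):
    APPLICABLE = "applicable"
    INAPPLICABLE = "inapplicable"


GEOMETRY_CHECK_IDS = (
    "slice_count",
    "in_plane_shape",
    "slice_thickness",
    "pixel_spacing",
    "table_position",
    "orientation",
)

CONTENT_CHECK_IDS = (
    "truncation",
    "shift",
    "scale",
    "foreign_object",
)


@dataclass
class QCCheck:
    check_id: str
    status: CheckStatus
    detail: str
    evidence: float


@dataclass
class QCReport:
    checks: list[QCCheck] = field(default_factory=list)

    @property
    def overall(self) -> Applicability:
        failed = any(c.status is CheckStatus.FAIL for c in self.checks)
        return Applicability.INAPPLICABLE if failed else Applicability.APPLICABLE

    def check(self, check_id: str) -> QCCheck:
        matches = [c for c in self.checks if c.check_id == check_id]
        if len(matches) != 1:
            raise KeyError(f"check id {check_id!r} appears {len(matches)} times")
        return matches[0]

    def failed_ids(self) -> list[str]:
        return [c.check_id for c in self.checks if c.status is CheckStatus.FAIL]

    def merged_with(self, other: "QCReport") -> "QCReport":
        return QCReport(checks=self.checks + other.checks)

    def to_dict(self) -> dict:
        return {
            "overall": self.overall.value,
            "checks": [
                {
                    "check_id": c.check_id,
                    "status": c.status.value,
                    "detail": c.detail,
                    "evidence": float(c.evidence),
                }
                for c in self.checks
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


@dataclass
class QCTolerances:
    """Thresholds for the pair checks.

    Geometry tolerances only absorb floating-point round-off: the protocol
    demands identical acquisition geometry. Content thresholds are
    configurable heuristics — the failure modes are qualitative and no
    published cutoff exists.
    """

    spacing_atol_mm: float = 1e-3
    origin_frac_voxel: float = 0.5
    truncation_border_frac: float = 0.005
    shift_fail_mm: float = 10.0
    scale_warn_band: tuple[float, float] = (0.97, 1.03)
    scale_fail_band: tuple[float, float] = (0.90, 1.10)
    foreign_object_min_mm3: float = 5_000.0


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def check_pair_geometry(
    rest: GridRaster, valsalva: GridRaster, tolerances: QCTolerances | None = None
) -> QCReport:
    """Compare acquisition geometry of the two scans.

    All comparisons are symmetric in the two arguments. A differing origin
    is reported as ``table_position``: the scans must be acquired without
    moving the patient table, and the stored origin is where a table move
    shows up.
    """
    tol = tolerances or QCTolerances()
    checks: list[QCCheck] = []

    nz_a, nz_b = rest.shape[2], valsalva.shape[2]
    checks.append(
        _binary_check(
            "slice_count",
            nz_a == nz_b,
            f"slice counts {nz_a} vs {nz_b}",
            abs(nz_a - nz_b),
        )
    )
    shape_diff = max(
        abs(rest.shape[0] - valsalva.shape[0]), abs(rest.shape[1] - valsalva.shape[1])
    )
    checks.append(
        _binary_check(
            "in_plane_shape",
            shape_diff == 0,
            f"in-plane shapes {rest.shape[:2]} vs {valsalva.shape[:2]}",
            shape_diff,
        )
    )
    dz = abs(rest.spacing[2] - valsalva.spacing[2])
    checks.append(
        _binary_check(
            "slice_thickness",
            dz <= tol.spacing_atol_mm,
            f"slice thickness {rest.spacing[2]:.4g} vs {valsalva.spacing[2]:.4g} mm",
            dz,
        )
    )
    dxy = float(np.max(np.abs(rest.spacing[:2] - valsalva.spacing[:2])))
    checks.append(
        _binary_check(
            "pixel_spacing",
            dxy <= tol.spacing_atol_mm,
            f"pixel spacing {rest.spacing[:2]} vs {valsalva.spacing[:2]} mm",
            dxy,
        )
    )
    origin_tol = tol.origin_frac_voxel * float(np.min(np.minimum(rest.spacing, valsalva.spacing)))
    dorigin = float(np.max(np.abs(rest.origin - valsalva.origin)))
    checks.append(
        _binary_check(
            "table_position",
            dorigin <= origin_tol,
            f"origin offset {dorigin:.3g} mm (tolerance {origin_tol:.3g} mm)",
            dorigin,
        )
    )
    same_orient = rest.axis_codes == valsalva.axis_codes
    checks.append(
        _binary_check(
            "orientation",
            same_orient,
            f"axis codes {rest.axis_codes!r} vs {valsalva.axis_codes!r}",
            0.0 if same_orient else 1.0,
        )
    )
    return QCReport(checks=checks)


def _binary_check(check_id: str, ok: bool, detail: str, evidence: float) -> QCCheck:
    return QCCheck(check_id, CheckStatus.PASS if ok else CheckStatus.FAIL, detail, float(evidence))


# ---------------------------------------------------------------------------
# content
# ---------------------------------------------------------------------------

def check_pair_content(
    rest_mask: BinaryMask,
    valsalva_mask: BinaryMask,
    thresholds: QCTolerances | None = None,
) -> QCReport:
    """Heuristic content checks on the two body masks (shared grid).

    truncation — body touches a lateral or anterior image border;
    shift — in-plane centroid offset between the masks beyond threshold;
    scale — in-plane bounding-box extent ratio outside the tolerance band
    (warn) or the gross band (fail; genuine Valsalva expansion changes the
    box slightly, only a reconstruction-scale mismatch fails);
    foreign_object — more than one sizeable connected component (arms).
    """
    tol = thresholds or QCTolerances()
    if not rest_mask.voxels.any() or not valsalva_mask.voxels.any():
        raise ValueError("content checks require non-empty body masks")
    if not rest_mask.same_grid(valsalva_mask, atol=1e-3):
        raise ValueError("content checks require masks on the same grid; run geometry checks first")

    checks: list[QCCheck] = []

    # (a) truncation: mask voxels on the lateral (x) or anterior (+y) borders
    frac = max(_border_fraction(rest_mask), _border_fraction(valsalva_mask))
    checks.append(
        _binary_check(
            "truncation",
            frac <= tol.truncation_border_frac,
            f"{100 * frac:.2f}% of body voxels on lateral/anterior borders "
            f"(threshold {100 * tol.truncation_border_frac:.2f}%)",
            frac,
        )
    )

    # (b) gross in-plane shift between the masks
    offset = valsalva_mask.centroid_world()[:2] - rest_mask.centroid_world()[:2]
    shift_mm = float(np.linalg.norm(offset))
    checks.append(
        _binary_check(
            "shift",
            shift_mm <= tol.shift_fail_mm,
            f"in-plane centroid offset {shift_mm:.1f} mm (threshold {tol.shift_fail_mm:.1f} mm)",
            shift_mm,
        )
    )

    # (c) gross in-plane scale mismatch via the lateral bounding-box extent.
    # Only the x extent is compared: genuine Valsalva expansion is anterior
    # (y) and would confound that axis, while a reconstruction zoom scales
    # both axes equally.
    ratio = _extent_ratio(rest_mask, valsalva_mask)[0]
    lo_w, hi_w = tol.scale_warn_band
    lo_f, hi_f = tol.scale_fail_band
    if lo_f <= ratio <= hi_f:
        status = CheckStatus.PASS if lo_w <= ratio <= hi_w else CheckStatus.WARN
    else:
        status = CheckStatus.FAIL
    checks.append(
        QCCheck(
            "scale",
            status,
            f"lateral extent ratio {ratio:.3f} "
            f"(warn outside {tol.scale_warn_band}, fail outside {tol.scale_fail_band})",
            float(ratio),
        )
    )

    # (d) foreign objects: detached sizeable components in either mask
    n_extra = max(
        _sizeable_components(rest_mask, tol.foreign_object_min_mm3),
        _sizeable_components(valsalva_mask, tol.foreign_object_min_mm3),
    ) - 1
    checks.append(
        _binary_check(
            "foreign_object",
            n_extra <= 0,
            f"{n_extra} detached component(s) above "
            f"{tol.foreign_object_min_mm3:.0f} mm^3 besides the body",
            max(n_extra, 0),
        )
    )
    return QCReport(checks=checks)


def _border_fraction(mask: BinaryMask) -> float:
    # Fraction of body SURFACE voxels sitting on the lateral (x) or anterior
    # (+y) image borders. Using the surface rather than the volume keeps the
    # measure independent of grid resolution: a truncation plane of area A
    # contributes about A / (total surface area) regardless of spacing.
    v = mask.voxels
    surface = v & ~ndimage.binary_erosion(v)
    border = int(surface[0].sum() + surface[-1].sum() + surface[:, -1].sum())
    return border / max(int(surface.sum()), 1)


def _extent_ratio(a: BinaryMask, b: BinaryMask) -> tuple[float, float]:
    def extents(m: BinaryMask) -> np.ndarray:
        idx = np.argwhere(m.voxels)
        span = idx.max(axis=0) - idx.min(axis=0) + 1
        return span * m.spacing

    ea, eb = extents(a), extents(b)
    return float(eb[0] / ea[0]), float(eb[1] / ea[1])


def _sizeable_components(mask: BinaryMask, min_mm3: float) -> int:
    labels, n = ndimage.label(mask.voxels, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return int(np.sum(sizes * mask.voxel_volume_mm3 >= min_mm3))
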