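"""Label-map volumetry, loss of domain, mesh-defect ratio, report slice.

Volumes come from a segmentation label map (cavity, rectus, three lateral
muscle layers, hernia sac). The loss-of-domain ratio follows the
Sabbagh convention

    LoD = 100 · V_hernia / (V_hernia + V_cavity)   [%]

which is recorded in the output provenance since other conventions exist.
Defect and mesh areas are intraoperative/manual measurements supplied by
the user; imaging does not produce them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabelMap

LOSS_OF_DOMAIN_CONVENTION = "sabbagh: hernia / (hernia + cavity)"


@dataclass
class HerniaMetrics:
    volumes_cm3: dict = field(default_factory=dict)  # class name -> cm³
    loss_of_domain_pct: float | None = None
    defect_area_cm2: float | None = None
    mesh_area_cm2: float | None = None
    mesh_defect_ratio: float | None = None
    hernia_slice_index: int | None = None
    convention: str = LOSS_OF_DOMAIN_CONVENTION

    def to_dict(self) -> dict:
        return {
            "volumes_cm3": dict(self.volumes_cm3),
            "loss_of_domain_pct": self.loss_of_domain_pct,
            "defect_area_cm2": self.defect_area_cm2,
            "mesh_area_cm2": self.mesh_area_cm2,
            "mesh_defect_ratio": self.mesh_defect_ratio,
            "hernia_slice_index": self.hernia_slice_index,
            "loss_of_domain_convention": self.convention,
        }


def label_volumes(labels: LabelMap) -> dict:
    """Per-class volumes in cm³ (voxel count × voxel volume)."""
    counts = np.bincount(labels.voxels.ravel(), minlength=max(labels.class_table) + 1)
    vox_cm3 = labels.voxel_volume_mm3 / 1000.0
    return {
        name: float(counts[cid]) * vox_cm3 for cid, name in sorted(labels.class_table.items())
    }


def loss_of_domain(v_hernia_cm3: float, v_cavity_cm3: float) -> float:
    """Loss of domain in percent: 100 · V_hernia / (V_hernia + V_cavity)."""
    if v_hernia_cm3 < 0 or v_cavity_cm3 < 0:
        raise ValueError("volumes must be non-negative")
    total = v_hernia_cm3 + v_cavity_cm3
    if total == 0:
        raise ValueError("loss of domain undefined: both volumes are zero")
    return 100.0 * v_hernia_cm3 / total


def mesh_defect_ratio(mesh_area_cm2: float, defect_area_cm2: float) -> float:
    """Implanted-mesh area divided by hernia-defect area (dimensionless).

    Within the GRIP framework a low ratio flags an elevated recurrence
    risk, particularly in elastic tissue.
    """
    if defect_area_cm2 <= 0:
        raise ValueError("defect area must be positive")
    return mesh_area_cm2 / defect_area_cm2


def select_hernia_slice(labels: LabelMap, axis: int = 2, hernia_class: int = 6) -> int:
    """Index of the slice with the largest hernia-sac cross-section.

    ``axis=2`` selects axial (transverse) slices in the canonical frame.
    Ties break towards the lowest index.
    """
    hern = labels.voxels == hernia_class
    if not hern.any():
        raise ValueError("hernia class is empty; no slice to select")
    other = tuple(a for a in range(3) if a != axis)
    counts = hern.sum(axis=other)
    return int(np.argmax(counts))


def compute_metrics(
    labels: LabelMap,
    defect_area_cm2: float | None = None,
    mesh_area_cm2: float | None = None,
    cavity_class: int = 1,
    hernia_class: int = 6,
) -> HerniaMetrics:
    """Full volumetry bundle from a label map plus optional manual areas."""
    vols = label_volumes(labels)
    names = labels.class_table
    v_hernia = vols[names[hernia_class]]
    v_cavity = vols[names[cavity_class]]
    lod = loss_of_domain(v_hernia, v_cavity) if (v_hernia + v_cavity) > 0 else None
    ratio = None
    if defect_area_cm2 is not None and mesh_area_cm2 is not None:
        ratio = mesh_defect_ratio(mesh_area_cm2, defect_area_cm2)
    slice_idx = select_hernia_slice(labels, hernia_class=hernia_class) if v_hernia > 0 else None
    return HerniaMetrics(
        volumes_cm3=vols,
        loss_of_domain_pct=lod,
        defect_area_cm2=defect_area_cm2,
        mesh_area_cm2=mesh_area_cm2,
        mesh_defect_ratio=ratio,
        hernia_slice_index=slice_idx,
    )
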