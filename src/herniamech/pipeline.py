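"""End-to-end orchestration: QC → masking → registration → strain →
surfaces → metrics → optional landmark validation, with report output.

The pipeline mirrors the clinical workflow: a scan pair is first screened
for applicability (a pair acquired with mismatched geometry or corrupted
content is rejected outright unless explicitly overridden), then the body
outlines are registered, the strain and instability statistics computed,
and everything written to an output directory as JSON metrics, NIfTI
fields and PLY surfaces plus a static report panel.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__
from .core import BinaryMask, LabelMap, Phase, ScanVolume
from .hernia_metrics import HerniaMetrics, compute_metrics, select_hernia_slice
from .landmark_validation import LandmarkErrorReport, LandmarkSet, compare_to_field
from .masking import body_mask, downscale_mask, qc_content_mask
from .qc import QCReport, QCTolerances, check_pair_content, check_pair_geometry
from .registration import (
    DisplacementField,
    RegistrationConfig,
    jacobian_determinant,
    register_masks,
    warp_mask,
)
from .scan_io import load_scan, resample_isotropic, save_nifti
from .strain_mechanics import StrainField, strain_from_field
from .surface_instability import (
    InstabilityResult,
    SurfaceMesh,
    colourize,
    extract_surface,
    map_displacement,
    map_scalar_volume,
    unstable_area,
)


class PipelineAbort(RuntimeError):
    """The scan pair failed QC and no override was requested."""

    def __init__(self, report: QCReport):
        self.report = report
        failing = ", ".join(report.failed_ids())
        super().__init__(
            f"scan pair is inapplicable; failing checks: {failing}. "
            "Re-acquire the scans or pass override_qc=True to proceed anyway."
        )


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults follow the clinical protocol
    (1 mm isotropic resampling, downscale factor 3, 15 mm threshold)."""

    rest_path: str | os.PathLike | None = None
    valsalva_path: str | os.PathLike | None = None
    labels_path: str | os.PathLike | None = None
    landmarks_path: str | os.PathLike | None = None
    out_dir: str | os.PathLike | None = None
    hu_threshold: float = -300.0
    resample_mm: float = 1.0
    downscale: int = 3
    threshold_mm: float = 15.0
    defect_area_cm2: float | None = None
    mesh_area_cm2: float | None = None
    registration: RegistrationConfig = dc_field(default_factory=RegistrationConfig)
    qc_tolerances: QCTolerances = dc_field(default_factory=QCTolerances)
    override_qc: bool = False
    write_fields: bool = True
    write_report: bool = True

    def config_hash(self) -> str:
        """Hash of the scientific settings only (paths excluded, so the
        same analysis on relocated data hashes identically)."""
        skip = {"rest_path", "valsalva_path", "labels_path", "landmarks_path", "out_dir"}
        payload = json.dumps(
            {
                k: v
                for k, v in self.__dict__.items()
                if k not in skip and not isinstance(v, (RegistrationConfig, QCTolerances))
            }
            | {"registration": self.registration.__dict__, "qc": self.qc_tolerances.__dict__},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    qc: QCReport
    field: DisplacementField | None = None
    strain: StrainField | None = None
    rest_surface: SurfaceMesh | None = None
    valsalva_surface: SurfaceMesh | None = None
    instability_rest: InstabilityResult | None = None
    instability_valsalva: InstabilityResult | None = None
    hernia: HerniaMetrics | None = None
    landmark_report: LandmarkErrorReport | None = None
    provenance: dict = dc_field(default_factory=dict)

    def metrics_dict(self) -> dict:
        out = {
            "provenance": self.provenance,
            "qc": self.qc.to_dict(),
        }
        if self.instability_rest is not None:
            out["instability_rest"] = self.instability_rest.to_dict()
            out["instability_valsalva"] = self.instability_valsalva.to_dict()
        if self.field is not None:
            out["registration"] = {
                "min_jacobian_on_body": self.provenance.get("min_jacobian_on_body"),
                "dice_warped_vs_valsalva": self.provenance.get("dice_warped_vs_valsalva"),
            }
        if self.hernia is not None:
            out["hernia_metrics"] = self.hernia.to_dict()
        if self.landmark_report is not None:
            out["landmark_validation"] = self.landmark_report.to_dict()
        return out

    def metrics_json(self) -> str:
        return json.dumps(self.metrics_dict(), indent=2, sort_keys=True)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean rasters."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return float(2.0 * np.logical_and(a, b).sum() / denom) if denom else 1.0


def run_pipeline(
    cfg: PipelineConfig,
    rest: ScanVolume | None = None,
    valsalva: ScanVolume | None = None,
    labels: LabelMap | None = None,
    landmarks: LandmarkSet | None = None,
) -> ResultBundle:
    """Run the full evaluation; in-memory inputs override configured paths."""
    if rest is None:
        rest = load_scan(cfg.rest_path, Phase.REST)
    if valsalva is None:
        valsalva = load_scan(cfg.valsalva_path, Phase.VALSALVA)
    if labels is None and cfg.labels_path:
        from .scan_io import _load_nifti  # label maps share the NIfTI reader

        vol = _load_nifti(Path(cfg.labels_path), Phase.REST)
        labels = LabelMap(vol.voxels.astype(np.uint8), vol.spacing, vol.origin)
    if landmarks is None and cfg.landmarks_path:
        landmarks = LandmarkSet.from_csv(cfg.landmarks_path)

    provenance: dict = {
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "threshold_mm": cfg.threshold_mm,
        "resample_mm": cfg.resample_mm,
        "downscale": cfg.downscale,
        "warnings": [],
    }

    # 1. geometry applicability
    qc = check_pair_geometry(rest, valsalva, cfg.qc_tolerances)
    if qc.overall.value == "inapplicable":
        if not cfg.override_qc:
            raise PipelineAbort(qc)
        provenance["warnings"].append("geometry QC overridden")
        return ResultBundle(qc=qc, provenance=provenance)

    # 2. isotropic resampling and content applicability
    rest_iso = resample_isotropic(rest, cfg.resample_mm)
    val_iso = resample_isotropic(valsalva, cfg.resample_mm)
    qc_rest = qc_content_mask(rest_iso, cfg.hu_threshold)
    qc_val = qc_content_mask(val_iso, cfg.hu_threshold)
    qc = qc.merged_with(check_pair_content(qc_rest, qc_val, cfg.qc_tolerances))
    if qc.overall.value == "inapplicable" and not cfg.override_qc:
        raise PipelineAbort(qc)

    # 3. body outlines and registration at the downscaled resolution
    rest_body = body_mask(rest_iso, cfg.hu_threshold)
    val_body = body_mask(val_iso, cfg.hu_threshold)
    rest_coarse = downscale_mask(rest_body, cfg.downscale)
    val_coarse = downscale_mask(val_body, cfg.downscale)
    field = register_masks(rest_coarse, val_coarse, cfg.registration)

    warped = warp_mask(rest_coarse, field)
    provenance["dice_warped_vs_valsalva"] = dice(warped.voxels, val_coarse.voxels)
    jac = jacobian_determinant(field)
    provenance["min_jacobian_on_body"] = float(jac[rest_coarse.voxels].min())

    # 4. strain on the registration grid
    strain = strain_from_field(field)

    # 5. surfaces, displacement mapping, instability statistic
    rest_surface = extract_surface(rest_body, Phase.REST)
    val_surface = extract_surface(val_body, Phase.VALSALVA)
    rest_surface = map_displacement(rest_surface, field)
    val_surface = map_displacement(val_surface, field)
    rest_surface = map_scalar_volume(rest_surface, strain.max_principal, strain, "max_principal_strain")
    val_surface = map_scalar_volume(val_surface, strain.max_principal, strain, "max_principal_strain")
    colourize(rest_surface, cfg.threshold_mm)
    colourize(val_surface, cfg.threshold_mm)
    inst_rest = unstable_area(rest_surface, cfg.threshold_mm)
    inst_val = unstable_area(val_surface, cfg.threshold_mm)

    # 6. volumetry and landmark validation
    hernia = None
    if labels is not None:
        hernia = compute_metrics(labels, cfg.defect_area_cm2, cfg.mesh_area_cm2)
    landmark_report = None
    if landmarks is not None:
        landmark_report = compare_to_field(landmarks, field)

    bundle = ResultBundle(
        qc=qc,
        field=field,
        strain=strain,
        rest_surface=rest_surface,
        valsalva_surface=val_surface,
        instability_rest=inst_rest,
        instability_valsalva=inst_val,
        hernia=hernia,
        landmark_report=landmark_report,
        provenance=provenance,
    )

    if cfg.out_dir is not None:
        write_outputs(bundle, cfg, labels=labels, ct=rest_iso)
    return bundle


def write_outputs(
    bundle: ResultBundle,
    cfg: PipelineConfig,
    labels: LabelMap | None = None,
    ct: ScanVolume | None = None,
) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.json").write_text(bundle.metrics_json())
    (out / "qc.json").write_text(bundle.qc.to_json())
    if cfg.write_fields and bundle.field is not None:
        save_nifti(bundle.field, out / "displacement_field.nii.gz")
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(bundle.strain.max_principal.astype(np.float32), bundle.strain.affine()),
            str(out / "max_principal_strain.nii.gz"),
        )
        # symmetric tensor as 6 components: E11, E22, E33, E12, E13, E23
        t = bundle.strain.tensors
        six = np.stack(
            [t[..., 0, 0], t[..., 1, 1], t[..., 2, 2], t[..., 0, 1], t[..., 0, 2], t[..., 1, 2]],
            axis=-1,
        ).astype(np.float32)
        nib.save(
            nib.Nifti1Image(six, bundle.strain.affine()), str(out / "strain_tensor.nii.gz")
        )
    if bundle.rest_surface is not None:
        bundle.rest_surface.export_ply(out / "surface_rest.ply")
        bundle.valsalva_surface.export_ply(out / "surface_valsalva.ply")
    if cfg.write_report:
        render_report(bundle, labels=labels, ct=ct, path=out / "report.png")


def render_report(
    bundle: ResultBundle,
    labels: LabelMap | None = None,
    ct: ScanVolume | None = None,
    path: str | os.PathLike = "report.png",
) -> dict:
    """Static snapshot panel: strain, displacement colouring, segmentation
    overlay and the CT cross-section with the largest hernia area.

    Returns a small dict describing the panel layout (used for report
    provenance and tests). Without a hernia class the CT panel falls back
    to the mid-volume slice, with a note.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    surfaces = {
        "rest": bundle.rest_surface,
        "valsalva": bundle.valsalva_surface,
    }
    info: dict = {"panels": [], "slice_note": None}
    slice_idx = None
    if labels is not None:
        try:
            slice_idx = select_hernia_slice(labels)
        except ValueError:
            slice_idx = None
    if slice_idx is None:
        ref = labels if labels is not None else ct
        slice_idx = ref.shape[2] // 2 if ref is not None else None
        info["slice_note"] = "no hernia class; falling back to the mid-volume slice"
    info["hernia_slice_index"] = slice_idx

    n_rows = len([s for s in surfaces.values() if s is not None])
    fig, axes = plt.subplots(max(n_rows, 1), 4, figsize=(16, 4 * max(n_rows, 1)), squeeze=False)
    for row, (phase, surf) in enumerate(s for s in surfaces.items() if s[1] is not None):
        x, z = surf.vertices[:, 0], surf.vertices[:, 2]
        axes[row][0].scatter(x, z, c=surf.scalars.get("max_principal_strain"), s=1, cmap="inferno")
        axes[row][0].set_title(f"{phase}: max principal strain")
        axes[row][1].scatter(x, z, c=surf.scalars.get("colour"), s=1)
        axes[row][1].set_title(f"{phase}: displacement (unstable wall)")
        if labels is not None and slice_idx is not None:
            axes[row][2].imshow(labels.voxels[:, :, min(slice_idx, labels.shape[2] - 1)].T,
                                origin="lower", cmap="tab10", vmin=0, vmax=9)
        axes[row][2].set_title(f"{phase}: segmentation")
        if ct is not None and slice_idx is not None:
            axes[row][3].imshow(ct.voxels[:, :, min(slice_idx, ct.shape[2] - 1)].T,
                                origin="lower", cmap="gray")
        axes[row][3].set_title(f"{phase}: CT slice {slice_idx}")
        for ax in axes[row]:
            ax.set_aspect("equal")
        info["panels"].append([f"{phase}:strain", f"{phase}:displacement",
                               f"{phase}:segmentation", f"{phase}:ct_slice"])
    fig.suptitle(f"threshold = {bundle.provenance.get('threshold_mm')} mm")
    fig.savefig(path, dpi=80)
    plt.close(fig)
    return info
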