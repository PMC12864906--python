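"""Hernia volumetry: class volumes, loss of domain, mesh-defect ratio.

Works on the phantom's segmentation label map (cavity, muscle layers,
hernia sac); the defect and mesh areas are intraoperative measurements
supplied by the surgeon.
"""

import herniamech as hm

bundle = hm.generate_phantom(hm.PhantomSpec(grid_spacing_mm=3.0, seed=0))
metrics = hm.compute_metrics(
    bundle.rest_labels, defect_area_cm2=220.0, mesh_area_cm2=1060.0
)

for name, vol in metrics.volumes_cm3.items():
    if vol > 0:
        print(f"{name:20s} {vol:9.1f} cm³")
print(f"loss of domain = {metrics.loss_of_domain_pct:.1f}%  ({metrics.convention})")
print(f"mesh-defect area ratio = {metrics.mesh_defect_ratio:.2f}")
print(f"largest hernia cross-section at axial slice {metrics.hernia_slice_index}")
# Loss of domain is the fraction of abdominal contents already living in
# the sac; a mesh-defect ratio well above 1 indicates the repair covers
# far more than the defect itself, as biomechanical guidelines require.
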