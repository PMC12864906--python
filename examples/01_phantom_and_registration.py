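"""Recover a known anterior bulge from a synthetic rest/Valsalva pair.

Builds a torso phantom whose Valsalva state is a 25 mm Gaussian bulge with
a closed-form displacement field, registers the two body masks, and
checks the recovered field against the ground truth.
"""

import herniamech as hm

bundle = hm.generate_phantom(hm.PhantomSpec(grid_spacing_mm=3.0, seed=0))
field = hm.register_masks(bundle.rest_mask, bundle.valsalva_mask)

warped = hm.warp_mask(bundle.rest_mask, field)
dice = hm.dice(warped.voxels, bundle.valsalva_mask.voxels)
jac = hm.jacobian_determinant(field)
report = hm.compare_to_field(bundle.landmarks, field)

print(f"Dice(warped rest, Valsalva) = {dice:.4f}")
print(f"min Jacobian determinant on the body = {jac[bundle.rest_mask.voxels].min():.3f}")
print(f"landmark error = {report.mean_abs_error_mm:.2f} ± {report.sd_abs_error_mm:.2f} mm "
      f"({report.mean_normalized_error_pct:.1f}% of the max displacement)")
# Dice near 1 means the recovered field truly transforms the rest outline
# into the Valsalva outline; a strictly positive Jacobian certifies the
# map is invertible (diffeomorphic); the landmark error is the same
# electrode-style validation used on patients.
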