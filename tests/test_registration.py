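"""Displacement-field operations and registration contracts."""

import numpy as np
import pytest

import herniamech as hm
from herniamech.registration import FieldSamplingError, invert_field, sample_field


def uniform_field(vec, shape=(10, 10, 10), spacing=1.0):
    v = np.broadcast_to(np.asarray(vec, float), shape + (3,)).copy()
    return hm.DisplacementField(v, np.full(3, spacing), np.zeros(3))


def linear_field(rate=0.2, shape=(21, 21, 21), spacing=1.0):
    """u_x = rate * x, other components zero."""
    idx = np.arange(shape[0]) * spacing
    v = np.zeros(shape + (3,))
    v[..., 0] = rate * idx[:, None, None]
    return hm.DisplacementField(v, np.full(3, spacing), np.zeros(3))


class TestSampleField:
    def test_constant_field_everywhere(self):
        f = uniform_field((5.0, 0.0, 0.0))
        out = sample_field(f, [(1.2, 3.4, 5.6), (8.0, 0.1, 2.0)])
        assert np.allclose(out, [(5, 0, 0), (5, 0, 0)])

    def test_linear_field_exact(self):
        f = linear_field(0.2)
        out = sample_field(f, [(10.0, 5.0, 5.0)])
        assert np.allclose(out, [(2.0, 0.0, 0.0)], atol=1e-12)

    def test_out_of_bounds_names_the_point(self):
        f = uniform_field((0, 0, 0))
        with pytest.raises(FieldSamplingError, match="99"):
            sample_field(f, [(99.0, 0.0, 0.0)])

    def test_phantom_closed_form_at_interior_points(self, phantom3):
        # dense 1 mm rasterisation of the analytic field near the bulge
        spec = phantom3.spec
        lo = np.array([-40.0, 40.0, -40.0])
        n = 81
        g = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        pts = lo + np.stack(g, -1) * 1.0
        f = hm.DisplacementField(spec.displacement(pts), np.ones(3), lo)
        rng = np.random.default_rng(3)
        q = lo + 5 + rng.uniform(0, 70, size=(20, 3))
        pred = sample_field(f, q)
        true = spec.displacement(q)
        assert np.abs(pred - true).max() < 0.2

    def test_field_rejects_nonfinite_vectors(self):
        v = np.zeros((4, 4, 4, 3))
        v[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            hm.DisplacementField(v, np.ones(3), np.zeros(3))


class TestWarpMask:
    def test_zero_field_is_identity(self, sphere50):
        f = uniform_field((0, 0, 0), shape=sphere50.shape, spacing=1.0)
        f.origin[:] = sphere50.origin
        out = hm.warp_mask(sphere50, f)
        assert np.array_equal(out.voxels, sphere50.voxels)
        assert out.provenance is hm.MaskProvenance.WARPED

    def test_uniform_translation_moves_centroid(self):
        v = np.zeros((30, 20, 20), bool)
        v[5:12, 5:12, 5:12] = True
        cube = hm.BinaryMask(v, np.ones(3), np.zeros(3))
        f = uniform_field((10.0, 0.0, 0.0), shape=cube.shape)
        out = hm.warp_mask(cube, f)
        delta = out.centroid_world() - cube.centroid_world()
        assert np.allclose(delta, (10.0, 0.0, 0.0), atol=0.3)

    def test_analytic_field_reproduces_valsalva_mask(self, phantom3):
        out = hm.warp_mask(phantom3.rest_mask, phantom3.field)
        assert hm.dice(out.voxels, phantom3.valsalva_mask.voxels) >= 0.97


class TestJacobian:
    def test_zero_field_gives_unity(self):
        f = uniform_field((0, 0, 0))
        assert np.allclose(hm.jacobian_determinant(f), 1.0)

    def test_uniform_stretch_exact(self):
        f = linear_field(0.1)
        jac = hm.jacobian_determinant(f)
        assert np.allclose(jac[1:-1], 1.1, atol=1e-12)

    def test_phantom_field_positive_on_body(self, phantom3):
        jac = hm.jacobian_determinant(phantom3.field)
        assert jac[phantom3.rest_mask.voxels].min() > 0


class TestInvertField:
    def test_inverse_of_translation(self):
        f = uniform_field((4.0, 0.0, 0.0), shape=(15, 15, 15))
        inv = invert_field(f)
        interior = inv.voxels[5:10, 5:10, 5:10]
        assert np.allclose(interior, (-4.0, 0.0, 0.0), atol=0.05)

    def test_composition_is_identity_on_phantom(self, phantom3):
        spec = phantom3.spec
        rng = np.random.default_rng(5)
        pts = rng.uniform(-60, 60, size=(50, 3)) + np.array([0, 40.0, 0])
        fwd = spec.displacement(pts)
        back = spec.inverse_displacement(pts + fwd)
        assert np.abs(fwd + back).max() < 0.02


class TestRegisterMasks:
    def test_grid_mismatch_is_geometry_error(self, phantom3):
        small = hm.downscale_mask(phantom3.rest_mask, 2)
        with pytest.raises(ValueError, match="grid"):
            hm.register_masks(phantom3.rest_mask, small)

    def test_recovered_field_transforms_rest_into_valsalva(self, phantom3, recovered_field):
        warped = hm.warp_mask(phantom3.rest_mask, recovered_field)
        assert hm.dice(warped.voxels, phantom3.valsalva_mask.voxels) >= 0.95

    def test_recovered_field_is_diffeomorphic(self, phantom3, recovered_field):
        jac = hm.jacobian_determinant(recovered_field)
        assert jac[phantom3.rest_mask.voxels].min() > 0

    def test_provenance_records_convergence(self, recovered_field):
        assert len(recovered_field.provenance["levels"]) == 3
        assert all("iterations_run" in lv for lv in recovered_field.provenance["levels"])

    def test_symmetry_swapping_phases_negates_displacements(self, phantom3, recovered_field):
        """Registering Valsalva onto rest recovers landmark displacement
        magnitudes consistent with the forward registration (symmetric
        formulation contract: within 10%)."""
        rev = hm.register_masks(phantom3.valsalva_mask, phantom3.rest_mask)
        fwd_mag = np.linalg.norm(
            hm.registration.sample_field_clamped(recovered_field, phantom3.landmarks.rest)[0], axis=1
        )
        rev_mag = np.linalg.norm(
            hm.registration.sample_field_clamped(rev, phantom3.landmarks.valsalva)[0], axis=1
        )
        max_disp = fwd_mag.max()
        assert np.abs(fwd_mag - rev_mag).mean() <= 0.10 * max_disp
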