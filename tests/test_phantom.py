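"""Phantom construction: determinism, analytic consistency, corruptions."""

import numpy as np
import pytest

import herniamech as hm


class TestDeterminism:
    def test_same_spec_and_seed_bit_identical(self):
        spec = hm.PhantomSpec(grid_spacing_mm=5.0, seed=42)
        a = hm.generate_phantom(spec)
        b = hm.generate_phantom(hm.PhantomSpec(grid_spacing_mm=5.0, seed=42))
        assert np.array_equal(a.rest_scan.voxels, b.rest_scan.voxels)
        assert np.array_equal(a.valsalva_scan.voxels, b.valsalva_scan.voxels)
        assert np.array_equal(a.field.voxels, b.field.voxels)
        assert a.ground_truth == b.ground_truth

    def test_seed_changes_noise_only(self):
        a = hm.generate_phantom(hm.PhantomSpec(grid_spacing_mm=5.0, seed=1))
        b = hm.generate_phantom(hm.PhantomSpec(grid_spacing_mm=5.0, seed=2))
        assert not np.array_equal(a.rest_scan.voxels, b.rest_scan.voxels)
        assert np.array_equal(a.rest_labels.voxels, b.rest_labels.voxels)


class TestAnalyticDeformation:
    def test_zero_amplitude_is_identity(self):
        spec = hm.PhantomSpec(grid_spacing_mm=5.0, bulge_amplitude_mm=0.0, noise_sd_hu=0.0)
        b = hm.generate_phantom(spec)
        assert np.array_equal(b.rest_scan.voxels, b.valsalva_scan.voxels)
        assert np.all(b.field.voxels == 0.0)

    def test_max_displacement_at_bulge_centre(self):
        spec = hm.PhantomSpec(bulge_amplitude_mm=40.0)
        u = spec.displacement(np.array(spec.bulge_centre_mm))
        assert np.linalg.norm(u) == pytest.approx(40.0)
        far = spec.displacement(np.array(spec.bulge_centre_mm) + 700.0)
        assert np.linalg.norm(far) < 1e-9

    def test_jacobian_positive_on_default_grid(self, phantom3):
        grad = phantom3.spec.displacement_gradient(
            phantom3.field.origin
            + np.stack(
                np.meshgrid(*[np.arange(n) for n in phantom3.field.shape], indexing="ij"), -1
            )
            * phantom3.field.spacing
        )
        det = np.linalg.det(np.eye(3) + grad)
        assert det.min() > 0

    def test_diffeomorphism_bound_enforced(self):
        with pytest.raises(ValueError, match="diffeomorphic"):
            hm.PhantomSpec(bulge_amplitude_mm=200.0, bulge_sigma_mm=(80.0, 40.0, 60.0))

    def test_closed_form_gradient_matches_finite_differences(self):
        spec = hm.PhantomSpec()
        p = np.array([10.0, 80.0, -20.0])
        h = 1e-5
        num = np.zeros((3, 3))
        for j in range(3):
            dp = np.zeros(3)
            dp[j] = h
            num[:, j] = (spec.displacement(p + dp) - spec.displacement(p - dp)) / (2 * h)
        assert np.allclose(spec.displacement_gradient(p), num, atol=1e-6)

    def test_analytic_strain_properties(self):
        spec = hm.PhantomSpec(bulge_amplitude_mm=25.0)
        centre = np.array(spec.bulge_centre_mm)
        far = spec.strain(centre + np.array([700.0, 0.0, 0.0]))
        assert np.abs(far).max() < 1e-12
        zero_spec = hm.PhantomSpec(bulge_amplitude_mm=0.0)
        assert np.abs(zero_spec.strain(centre)).max() == 0.0
        e = spec.strain(centre + np.array([0.0, -40.0, 0.0]))
        assert np.abs(e - e.T).max() < 1e-15


class TestGroundTruthConsistency:
    def test_rasterised_field_matches_closed_form_at_voxel_centres(self, phantom3):
        g = np.meshgrid(*[np.arange(n) for n in phantom3.field.shape], indexing="ij")
        pts = phantom3.field.origin + np.stack(g, -1) * phantom3.field.spacing
        assert np.allclose(phantom3.field.voxels, phantom3.spec.displacement(pts), atol=1e-12)

    def test_warping_rest_mask_reproduces_valsalva_mask(self, phantom3):
        warped = hm.warp_mask(phantom3.rest_mask, phantom3.field)
        assert hm.dice(warped.voxels, phantom3.valsalva_mask.voxels) >= 0.99

    def test_surface_pipeline_reproduces_ground_truth_area(self, phantom_nohernia):
        b = phantom_nohernia
        mesh = hm.map_displacement(hm.extract_surface(b.rest_mask, "rest"), b.field)
        res = hm.unstable_area(mesh, b.ground_truth["threshold_mm"])
        assert res.unstable_area_cm2 == pytest.approx(
            b.ground_truth["unstable_area_cm2"], rel=0.05
        )

    def test_electrodes_lie_on_rest_surface_grid(self, phantom3):
        lm = phantom3.landmarks
        a, bb, c = phantom3.spec.semi_axes_mm
        on_surface = (
            (lm.rest[:, 0] / a) ** 2 + (lm.rest[:, 1] / bb) ** 2 + (lm.rest[:, 2] / c) ** 2
        )
        assert np.allclose(on_surface, 1.0, atol=1e-9)
        xs = np.unique(np.round(lm.rest[:, 0], 6))
        assert np.allclose(np.diff(xs), phantom3.spec.electrode_spacing_mm)


class TestDegradePair:
    def test_unknown_mode_rejected(self, phantom3):
        with pytest.raises(ValueError, match="unknown corruption mode"):
            hm.degrade_pair(phantom3, "gamma", 1.0)

    def test_slice_mismatch_changes_slice_count_only(self, phantom3):
        rest, val = hm.degrade_pair(phantom3, "slice_mismatch", 3)
        assert rest.shape[2] - val.shape[2] == 3
        assert rest.shape[:2] == val.shape[:2]

    def test_shift_moves_content_not_metadata(self, phantom3):
        rest, val = hm.degrade_pair(phantom3, "shift", 20.0)
        assert np.allclose(val.origin, phantom3.valsalva_scan.origin)
        com_before = np.argwhere(phantom3.valsalva_scan.voxels > -500).mean(0)
        com_after = np.argwhere(val.voxels > -500).mean(0)
        assert (com_after[0] - com_before[0]) * val.spacing[0] == pytest.approx(20.0, abs=2.0)
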