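"""Surface extraction, displacement mapping and the unstable-wall area."""

import numpy as np
import pytest

import herniamech as hm
from herniamech.core import BinaryMask

from conftest import make_sphere_mask


def sphere_mesh(radius=100.0, spacing=1.25):
    return hm.extract_surface(make_sphere_mask(radius, spacing, pad_mm=8.0))


def with_displacement(mesh, values):
    mesh.scalars["displacement_mm"] = np.asarray(values, dtype=float)
    return mesh


class TestExtractSurface:
    def test_sphere_area_analytic(self, sphere50):
        mesh = hm.extract_surface(sphere50)
        true = 4 * np.pi * 50.0**2
        assert abs(mesh.area_mm2() - true) / true < 0.03

    def test_cube_enclosed_volume_analytic(self):
        v = np.zeros((30, 30, 30), bool)
        v[5:25, 5:25, 5:25] = True
        mesh = hm.extract_surface(BinaryMask(v, np.ones(3), np.zeros(3)))
        assert abs(abs(mesh.to_trimesh().volume) - 8000.0) / 8000.0 < 0.05

    def test_single_voxel_gives_closed_mesh(self):
        v = np.zeros((5, 5, 5), bool)
        v[2, 2, 2] = True
        mesh = hm.extract_surface(BinaryMask(v, np.ones(3), np.zeros(3)))
        assert mesh.to_trimesh().is_watertight
        assert 1.0 < mesh.area_mm2() < 30.0  # of the order of a voxel's surface

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hm.extract_surface(BinaryMask(np.zeros((4, 4, 4), bool), np.ones(3), np.zeros(3)))

    def test_area_invariant_under_rigid_motion(self, sphere50):
        mesh = hm.extract_surface(sphere50)
        th = np.deg2rad(37.0)
        r = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        moved = hm.SurfaceMesh(mesh.vertices @ r.T + [10, -4, 2], mesh.triangles)
        assert moved.area_mm2() == pytest.approx(mesh.area_mm2(), rel=1e-6)


class TestMapDisplacement:
    def test_zero_field_maps_zero(self, sphere50):
        mesh = hm.extract_surface(sphere50)
        f = hm.DisplacementField(
            np.zeros(sphere50.shape + (3,)), sphere50.spacing, sphere50.origin
        )
        out = hm.map_displacement(mesh, f)
        assert np.allclose(out.scalars["displacement_mm"], 0.0)

    def test_uniform_translation_maps_magnitude(self, sphere50):
        mesh = hm.extract_surface(sphere50)
        v = np.broadcast_to([17.0, 0.0, 0.0], sphere50.shape + (3,)).copy()
        f = hm.DisplacementField(v, sphere50.spacing, sphere50.origin)
        out = hm.map_displacement(mesh, f)
        assert np.allclose(out.scalars["displacement_mm"], 17.0)

    def test_phantom_closed_form_within_half_mm(self, phantom3):
        mesh = hm.extract_surface(phantom3.rest_mask, "rest")
        out = hm.map_displacement(mesh, phantom3.field)
        true = np.linalg.norm(phantom3.spec.displacement(mesh.vertices), axis=1)
        assert np.abs(out.scalars["displacement_mm"] - true).max() < 0.5


class TestUnstableArea:
    def test_all_below_threshold_gives_zero(self):
        mesh = with_displacement(sphere_mesh(50.0, 2.0), None)
        mesh.scalars["displacement_mm"] = np.full(len(mesh.vertices), 5.0)
        res = hm.unstable_area(mesh, 15.0)
        assert res.unstable_area_cm2 == 0.0
        assert res.max_displacement_mm == 5.0

    def test_spherical_cap_analytic(self):
        mesh = sphere_mesh(100.0, 1.25)
        r = np.linalg.norm(mesh.vertices, axis=1)
        theta = np.arccos(np.clip(mesh.vertices[:, 2] / r, -1, 1))
        with_displacement(mesh, np.where(theta < np.deg2rad(30.0), 20.0, 5.0))
        res = hm.unstable_area(mesh, 15.0)
        true_cm2 = 2 * np.pi * 100.0**2 * (1 - np.cos(np.deg2rad(30.0))) / 100.0
        assert res.unstable_area_cm2 == pytest.approx(true_cm2, rel=0.05)

    def test_tiny_threshold_captures_everything(self, phantom3):
        mesh = hm.extract_surface(phantom3.rest_mask, "rest")
        mesh = hm.map_displacement(mesh, phantom3.field)
        mesh.scalars["displacement_mm"] += 0.01  # field is ~0 posteriorly
        res = hm.unstable_area(mesh, 0.001)
        assert res.unstable_area_cm2 == pytest.approx(res.total_area_cm2, rel=1e-6)

    def test_monotone_in_threshold(self, phantom3):
        mesh = hm.extract_surface(phantom3.rest_mask, "rest")
        mesh = hm.map_displacement(mesh, phantom3.field)
        areas = [hm.unstable_area(mesh, t).unstable_area_cm2 for t in (5, 10, 15, 20, 24)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_partitions_total_area_exactly(self, phantom3):
        mesh = hm.extract_surface(phantom3.rest_mask, "rest")
        mesh = hm.map_displacement(mesh, phantom3.field)
        res = hm.unstable_area(mesh, 15.0)
        disp = mesh.scalars["displacement_mm"]
        areas = mesh.triangle_areas()
        stable = areas[disp[mesh.triangles].mean(axis=1) <= 15.0].sum() / 100.0
        assert res.unstable_area_cm2 + stable == pytest.approx(res.total_area_cm2, abs=1e-9)

    def test_rest_and_valsalva_surfaces_agree(self, phantom3):
        rest = hm.map_displacement(
            hm.extract_surface(phantom3.rest_mask, "rest"), phantom3.field
        )
        val = hm.map_displacement(
            hm.extract_surface(phantom3.valsalva_mask, "valsalva"), phantom3.field
        )
        a = hm.unstable_area(rest, 15.0).unstable_area_cm2
        b = hm.unstable_area(val, 15.0).unstable_area_cm2
        assert abs(a - b) / a < 0.15

    def test_missing_channel_rejected(self, sphere50):
        mesh = hm.extract_surface(sphere50)
        with pytest.raises(ValueError, match="displacement_mm"):
            hm.unstable_area(mesh, 15.0)


class TestColourize:
    def setup_mesh(self):
        mesh = sphere_mesh(50.0, 2.0)
        n = len(mesh.vertices)
        d = np.linspace(0.0, 40.0, n)
        return with_displacement(mesh, d), d

    def test_two_regime_ramp_endpoints(self):
        mesh, d = self.setup_mesh()
        colours = hm.colourize(mesh, 15.0)
        assert np.allclose(colours[np.argmin(d)], (0, 0, 1))  # deepest blue at rest
        assert np.allclose(colours[np.argmax(d)], (1, 1, 1))  # white at max

    def test_discontinuity_at_threshold(self):
        mesh, _ = self.setup_mesh()
        eps = 1e-3
        mesh.scalars["displacement_mm"][:2] = [15.0 - eps, 15.0 + eps]
        colours = hm.colourize(mesh, 15.0)
        assert colours[0][2] == 1.0 and colours[0][0] == 0.0  # cyan side: blue channel full
        assert colours[1][0] == 1.0 and colours[1][2] < 0.5  # red side

    def test_missing_channel_rejected(self, sphere50):
        with pytest.raises(ValueError, match="displacement_mm"):
            hm.colourize(hm.extract_surface(sphere50), 15.0)
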