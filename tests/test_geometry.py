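"""Cervical plane fitting, canonical orientation and silhouette projection."""

import numpy as np
import pytest
import trimesh

from dentmorph.geometry import (OrientationError, Plane, PlaneFitError, fit_cervical_plane,
                                orient_specimen, project_silhouette)
from dentmorph.outlines import area_centroid, radial_pseudolandmarks
from dentmorph.synthetic import generate_cervical_points


class TestPlaneFit:
    def test_flat_z0(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.normal(size=20), rng.normal(size=20), np.zeros(20)])
        p = fit_cervical_plane(pts)
        np.testing.assert_allclose(p.normal, [0, 0, 1], atol=1e-12)
        assert p.offset == pytest.approx(0.0, abs=1e-12)
        assert p.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_tilted_exact_plane(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        pts = np.column_stack([x, y, 1.0 + 0.5 * x])
        p = fit_cervical_plane(pts)
        expect = np.array([-0.5, 0.0, 1.0])
        expect /= np.linalg.norm(expect)
        np.testing.assert_allclose(p.normal, expect, atol=1e-9)
        assert p.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_matches_svd_oracle_on_noisy_points(self):
        pts = generate_cervical_points([0.1, 0.2, 0.97], 3.0, n=100, noise_sd=0.05, seed=8)
        p = fit_cervical_plane(pts)
        c = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(c)
        oracle_n = vt[2] if vt[2][2] > 0 else -vt[2]
        np.testing.assert_allclose(p.normal, oracle_n, atol=1e-8)
        assert p.offset == pytest.approx(pts.mean(axis=0) @ oracle_n, abs=1e-8)

    def test_collinear_raises(self):
        t = np.linspace(0, 1, 10)
        pts = np.column_stack([t, 2 * t, 3 * t])
        with pytest.raises(PlaneFitError):
            fit_cervical_plane(pts)

    def test_residual_zero_iff_coplanar(self):
        pts = generate_cervical_points([0, 0, 1], 0.0, n=40, noise_sd=0.02, seed=3)
        assert fit_cervical_plane(pts).rms_residual > 1e-9


def _toy_crown(radius=4.0, height=5.0):
    """Cylindrical stand-in crown with cervical ellipse at z=0."""
    mesh = trimesh.creation.cylinder(radius=radius, height=height, sections=64)
    mesh.apply_translation([0, 0, height / 2.0])
    cerv = generate_cervical_points([0, 0, 1], 0.0, n=48, noise_sd=0.0, seed=0,
                                    semi_axes=(radius, radius * 0.9))
    return mesh, cerv


class TestOrientation:
    def test_canonical_mesh_gives_identity_frame(self):
        mesh, cerv = _toy_crown()
        out, frame = orient_specimen(mesh, cerv, [1, 0, 0], [0, 1, 0], side="left")
        assert frame.is_identity
        np.testing.assert_allclose(out.vertices, mesh.vertices, atol=1e-9)

    def test_round_trip_random_rotation(self):
        mesh, cerv = _toy_crown()
        rng = np.random.default_rng(42)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        R = trimesh.transformations.quaternion_matrix(q)[:3, :3]
        shift = np.array([3.0, -2.0, 7.0])
        rot = mesh.copy()
        rot.vertices = mesh.vertices @ R.T + shift
        out, frame = orient_specimen(rot, cerv @ R.T + shift,
                                     R @ [1, 0, 0], R @ [0, 1, 0], side="left")
        np.testing.assert_allclose(out.vertices, mesh.vertices, atol=1e-6)
        assert not frame.mirrored

    def test_orientation_idempotent(self):
        mesh, cerv = _toy_crown()
        once, _ = orient_specimen(mesh, cerv, [1, 0, 0], [0, 1, 0])
        twice, frame2 = orient_specimen(once, cerv, [1, 0, 0], [0, 1, 0])
        assert frame2.is_identity
        np.testing.assert_allclose(twice.vertices, once.vertices, atol=1e-9)

    def test_right_side_mirrors_to_left_convention(self):
        mesh, cerv = _toy_crown()
        # scale x asymmetrically to break symmetry
        mesh.vertices[:, 0] *= 1.2
        cerv_a = cerv.copy()
        right = mesh.copy()
        right.vertices = mesh.vertices * [-1, 1, 1]
        right.faces = right.faces[:, ::-1]
        out_l, _ = orient_specimen(mesh, cerv_a, [1, 0, 0], [0, 1, 0], side="left")
        out_r, frame_r = orient_specimen(right, cerv_a * [-1, 1, 1],
                                         [-1, 0, 0], [0, 1, 0], side="right")
        assert frame_r.mirrored
        sil_l = project_silhouette(out_l, 0.05)
        sil_r = project_silhouette(out_r, 0.05)
        lm_l = radial_pseudolandmarks(sil_l)
        lm_r = radial_pseudolandmarks(sil_r)
        np.testing.assert_allclose(lm_l.points, lm_r.points, atol=1e-6)

    def test_degenerate_hint_raises(self):
        mesh, cerv = _toy_crown()
        with pytest.raises(OrientationError):
            orient_specimen(mesh, cerv, [0, 0, 1], [0, 1, 0])


class TestSilhouette:
    def test_unit_cube_square_outline(self):
        box = trimesh.creation.box(extents=[1, 1, 1])
        box.apply_translation([0.5, 0.5, 0.5])
        res = 0.01
        sil = project_silhouette(box, res)
        area, _ = area_centroid(sil)
        perimeter = 4.0
        assert abs(area - 1.0) <= 2 * res * perimeter

    def test_cylinder_circle_area_within_1pct(self):
        cyl = trimesh.creation.cylinder(radius=3.0, height=2.0, sections=512)
        cyl.apply_translation([0, 0, 1.0])
        sil = project_silhouette(cyl, 0.02)
        area, _ = area_centroid(sil)
        assert abs(area - 9 * np.pi) / (9 * np.pi) < 0.01

    def test_sphere_equatorial_silhouette(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        sph.apply_translation([0, 0, 1.5])
        sil = project_silhouette(sph, 0.02)
        radii = np.linalg.norm(sil.vertices - sil.vertices.mean(axis=0), axis=1)
        assert np.median(radii) == pytest.approx(1.0, abs=0.03)

    def test_rotation_about_z_preserves_area(self):
        cyl = trimesh.creation.cylinder(radius=2.0, height=2.0, sections=256)
        cyl.apply_translation([0.5, 0.2, 1.0])  # off-axis so rotation matters
        a0, _ = area_centroid(project_silhouette(cyl, 0.02))
        rot = cyl.copy()
        ang = np.deg2rad(37.0)
        Rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                       [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        rot.vertices = cyl.vertices @ Rz.T
        a1, _ = area_centroid(project_silhouette(rot, 0.02))
        assert abs(a0 - a1) / a0 < 0.01
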