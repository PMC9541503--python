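"""Radial pseudo-landmarking, centroid size and crown diameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dentmorph.outlines import (CrownDiameters, LandmarkConfiguration, Outline2D,
                                OutlineGeometryError, area_centroid, centroid_size,
                                crown_diameters, normalize_configuration,
                                radial_pseudolandmarks)

from .conftest import circle_outline, ellipse_outline


class TestAreaCentroid:
    @pytest.mark.parametrize("verts, area, centroid", [
        ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0, (0.5, 0.5)),
        ([(0, 0), (3, 0), (0, 3)], 4.5, (1.0, 1.0)),
    ])
    def test_toy_polygons_exact(self, verts, area, centroid):
        a, c = area_centroid(Outline2D(np.array(verts, dtype=float)))
        assert a == pytest.approx(area, abs=1e-12)
        assert c == pytest.approx(centroid, abs=1e-12)

    def test_l_shape_matches_rectangle_decomposition(self):
        # L hexomino: 2x3 rectangle minus 1x2 notch = two rectangles
        # R1 = [0,3]x[0,1] (area 3, centroid (1.5, 0.5)); R2 = [0,1]x[1,2]
        verts = np.array([(0, 0), (3, 0), (3, 1), (1, 1), (1, 2), (0, 2)], dtype=float)
        a1, c1 = 3.0, np.array([1.5, 0.5])
        a2, c2 = 1.0, np.array([0.5, 1.5])
        a_expect = a1 + a2
        c_expect = (a1 * c1 + a2 * c2) / a_expect
        a, c = area_centroid(Outline2D(verts))
        assert a == pytest.approx(a_expect, abs=1e-12)
        np.testing.assert_allclose(c, c_expect, atol=1e-12)

    def test_orientation_independent(self):
        verts = np.array([(0, 0), (3, 0), (0, 3)], dtype=float)
        a_ccw, _ = area_centroid(Outline2D(verts))
        a_cw, _ = area_centroid(Outline2D(verts[::-1]))
        assert a_ccw == pytest.approx(a_cw)

    def test_degenerate_area_raises(self):
        line = np.array([(0, 0), (1, 0), (2, 0)], dtype=float)
        with pytest.raises(OutlineGeometryError):
            area_centroid(Outline2D(line))


def _brute_force_farthest(outline: Outline2D, origin: np.ndarray, theta: float) -> np.ndarray:
    """Independent oracle: test every boundary segment for ray intersection."""
    d = np.array([np.cos(theta), np.sin(theta)])
    verts = outline.vertices
    best_t = -1.0
    n = len(verts)
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        e = b - a
        denom = d[0] * (-e[1]) + d[1] * e[0]
        if abs(denom) < 1e-15:
            continue
        rel = a - origin
        t = (rel[0] * (-e[1]) + rel[1] * e[0]) / denom
        s = (d[0] * rel[1] - d[1] * rel[0]) / denom
        if t > 1e-12 and -1e-12 <= s <= 1 + 1e-12:
            best_t = max(best_t, t)
    assert best_t > 0
    return origin + best_t * d - origin


class TestRadialPseudolandmarks:
    def test_circle_all_radii_equal(self):
        lm = radial_pseudolandmarks(circle_outline(2.0, n=2000))
        radii = np.linalg.norm(lm.points, axis=1)
        np.testing.assert_allclose(radii, 2.0, atol=1e-3)

    def test_first_landmark_on_buccal_y_axis(self):
        lm = radial_pseudolandmarks(ellipse_outline(5.0, 4.0))
        assert lm.points[0][0] == pytest.approx(0.0, abs=1e-6)
        assert lm.points[0][1] > 0

    def test_ellipse_matches_polar_radius(self):
        a, b = 5.0, 4.0
        lm = radial_pseudolandmarks(ellipse_outline(a, b, n=8000))
        np.testing.assert_allclose(lm.points[0], [0.0, b], atol=1e-3)
        np.testing.assert_allclose(lm.points[4], [a, 0.0], atol=1e-3)
        for i, p in enumerate(lm.points):
            th = np.deg2rad(90.0 - i * 22.5)
            r_true = a * b / np.hypot(a * np.sin(th), b * np.cos(th))
            assert np.linalg.norm(p) == pytest.approx(r_true, abs=1e-3)

    def test_clockwise_ordering(self):
        lm = radial_pseudolandmarks(circle_outline(1.0, n=1000))
        ang = np.unwrap(np.arctan2(lm.points[:, 1], lm.points[:, 0]))
        assert np.all(np.diff(ang) < 0)  # buccal -> mesial -> lingual -> distal

    def test_star_polygon_farthest_crossing(self):
        # 5-pointed star (non-convex): some rays cross the boundary 3 times
        k_spikes = 5
        th = np.linspace(0, 2 * np.pi, 2 * k_spikes, endpoint=False) + np.pi / 2
        r = np.where(np.arange(2 * k_spikes) % 2 == 0, 3.0, 1.2)
        star = Outline2D(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        _, centroid = area_centroid(star)
        lm = radial_pseudolandmarks(star)
        for i, p in enumerate(lm.points):
            theta = np.deg2rad(90.0 - i * 22.5)
            expect = _brute_force_farthest(star, centroid, theta)
            np.testing.assert_allclose(p, expect, atol=1e-9)

    def test_invariant_to_starting_vertex(self):
        out = ellipse_outline(5.0, 4.0, n=1000)
        rolled = Outline2D(np.roll(out.vertices, 137, axis=0))
        lm1 = radial_pseudolandmarks(out)
        lm2 = radial_pseudolandmarks(rolled)
        np.testing.assert_allclose(lm1.points, lm2.points, atol=1e-9)

    def test_refinement_stability(self):
        lm_coarse = radial_pseudolandmarks(ellipse_outline(5.0, 4.0, n=2000))
        lm_fine = radial_pseudolandmarks(ellipse_outline(5.0, 4.0, n=16000))
        assert np.max(np.linalg.norm(lm_coarse.points - lm_fine.points, axis=1)) < 1e-3

    def test_centroid_outside_raises(self):
        # thin crescent whose area centroid falls outside the polygon
        th = np.linspace(-0.45 * np.pi, 0.45 * np.pi, 60)
        outer = np.column_stack([5 * np.cos(th), 5 * np.sin(th)])
        inner = np.column_stack([4.8 * np.cos(th[::-1]), 4.8 * np.sin(th[::-1])])
        crescent = Outline2D(np.vstack([outer, inner])).ensure_ccw()
        with pytest.raises(OutlineGeometryError):
            radial_pseudolandmarks(crescent)


class TestNormalization:
    def test_unit_circle_centroid_size_is_four(self):
        lm = radial_pseudolandmarks(circle_outline(1.0, n=4000))
        assert lm.centroid_size == pytest.approx(4.0, abs=1e-3)
        norm = normalize_configuration(lm)
        np.testing.assert_allclose(np.linalg.norm(norm.points, axis=1), 0.25, atol=1e-3)

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(16, 2))
        cs_direct = np.sqrt(sum(np.sum((p - pts.mean(axis=0)) ** 2) for p in pts))
        assert centroid_size(pts) == pytest.approx(cs_direct, abs=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(16, 2))
        a = normalize_configuration(
            LandmarkConfiguration(points=pts, centroid_size=centroid_size(pts)))
        b = normalize_configuration(
            LandmarkConfiguration(points=pts * scale,
                                  centroid_size=centroid_size(pts * scale)))
        np.testing.assert_allclose(a.points, b.points, atol=1e-9)

    def test_double_normalization_rejected(self):
        pts = np.random.default_rng(0).normal(size=(16, 2))
        cfg = normalize_configuration(
            LandmarkConfiguration(points=pts, centroid_size=centroid_size(pts)))
        with pytest.raises(ValueError):
            normalize_configuration(cfg)


class TestCrownDiameters:
    def test_unit_square(self):
        d = crown_diameters(Outline2D(np.array([(0, 0), (1, 0), (1, 1), (0, 1)], float)))
        assert (d.MD, d.BL) == (1.0, 1.0)

    def test_ellipse(self):
        d = crown_diameters(ellipse_outline(5.0, 4.0))
        assert d.MD == pytest.approx(10.0, abs=1e-4)
        assert d.BL == pytest.approx(8.0, abs=1e-4)

    def test_positive_invariant(self):
        with pytest.raises(ValueError):
            CrownDiameters(MD=0.0, BL=1.0)
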