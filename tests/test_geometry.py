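"""Tooth polygon construction, interior angles, apex/base labels, teeth."""

import numpy as np
import pytest

from leaftooth import (
    CornerPoint,
    GeometryError,
    MarginContour,
    ToothPolygon,
    build_teeth,
    classify_vertices,
    interior_angles,
    order_corners,
)
from leaftooth.geometry import APEX, BASE, refine_polygon


def _circle_contour(n=360, radius=100.0, center=(150.0, 150.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [np.round(center[0] + radius * np.cos(t)), np.round(center[1] + radius * np.sin(t))]
    ).astype(int)
    # deduplicate consecutive equal pixels from rounding
    keep = np.ones(len(pts), bool)
    keep[1:] = (np.diff(pts, axis=0) != 0).any(axis=1)
    return MarginContour(points=pts[keep])


def _corners_at(contour, indices):
    return [
        CornerPoint(row=int(contour.points[i][0]), col=int(contour.points[i][1]), response=1.0)
        for i in indices
    ]


def _star(n_spikes, r_out=10.0, r_in=4.0):
    t = np.linspace(0, 2 * np.pi, 2 * n_spikes, endpoint=False)
    r = np.where(np.arange(2 * n_spikes) % 2 == 0, r_out, r_in)
    return np.column_stack([r * np.sin(t), r * np.cos(t)])


from leaftooth.experiments import random_simple_polygon as _random_star_polygon


class TestOrderCorners:
    def test_sorted_by_arc_position(self):
        contour = _circle_contour()
        poly = order_corners(_corners_at(contour, [200, 10, 80, 150]), contour)
        assert sorted(poly.contour_indices.tolist()) == poly.contour_indices.tolist() or (
            poly.contour_indices.tolist() == sorted(poly.contour_indices.tolist(), reverse=True)
        )

    def test_orientation_normalized(self):
        contour = _circle_contour()
        poly = order_corners(_corners_at(contour, [10, 120, 300, 200]), contour)
        assert poly.signed_area() > 0

    def test_duplicates_merged_with_warning(self):
        contour = _circle_contour()
        with pytest.warns(UserWarning, match="duplicate"):
            poly = order_corners(_corners_at(contour, [10, 10, 120, 300]), contour)
        assert len(poly) == 3

    def test_too_few_corners(self):
        contour = _circle_contour()
        with pytest.raises(GeometryError):
            order_corners(_corners_at(contour, [5, 50]), contour)

    def test_square_from_contour_recovers_area(self):
        contour = _circle_contour()
        n = len(contour.points)
        idx = [0, n // 4, n // 2, 3 * n // 4]
        poly = order_corners(_corners_at(contour, idx), contour)
        v = poly.vertices
        side = np.hypot(*(v[1] - v[0]))
        assert abs(abs(poly.signed_area()) / (0.5 * side**2 * 2) - 1) < 0.05


class TestInteriorAngles:
    def test_unit_square_all_right_angles(self):
        poly = ToothPolygon(vertices=np.array([[0, 0], [0, 1], [1, 1], [1, 0]], float))
        if poly.signed_area() < 0:
            poly.vertices = poly.vertices[::-1].copy()
        assert interior_angles(poly) == pytest.approx([90.0] * 4)

    def test_triangle_angles_sum_to_180(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = rng.uniform(0, 10, (3, 2))
            poly = ToothPolygon(vertices=v)
            if abs(poly.signed_area()) < 1e-6:
                continue
            if poly.signed_area() < 0:
                poly.vertices = poly.vertices[::-1].copy()
            assert interior_angles(poly).sum() == pytest.approx(180.0)

    def test_dart_has_exactly_one_reflex_vertex(self):
        v = np.array([[0, 0], [4, 0], [1, 1], [0, 4]], float)
        poly = ToothPolygon(vertices=v)
        if poly.signed_area() < 0:
            poly.vertices = poly.vertices[::-1].copy()
        ang = interior_angles(poly)
        assert (ang > 180).sum() == 1
        # oracle: reflex vertices via edge-vector cross products must agree
        w = poly.vertices
        cross = []
        for i in range(4):
            a = w[i] - w[i - 1]
            b = w[(i + 1) % 4] - w[i]
            cross.append(a[1] * b[0] - a[0] * b[1])
        assert (np.array(cross) < 0).sum() == 1

    def test_angle_sum_random_star_polygons(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 101))
            poly = ToothPolygon(vertices=_random_star_polygon(rng, n))
            if poly.signed_area() < 0:
                poly.vertices = poly.vertices[::-1].copy()
            total = interior_angles(poly).sum()
            assert abs(total / ((n - 2) * 180.0) - 1) < 1e-6

    def test_coincident_vertices_raise(self):
        poly = ToothPolygon(vertices=np.array([[0, 0], [0, 0], [1, 1], [0, 2]], float))
        with pytest.raises(GeometryError):
            interior_angles(poly)


class TestClassifyVertices:
    def test_convex_polygon_all_apex(self):
        poly = ToothPolygon(vertices=_random_star_polygon(np.random.default_rng(3), 8))
        # convex hull of the points is convex by construction below
        from scipy.spatial import ConvexHull

        hull = ConvexHull(poly.vertices)
        poly = ToothPolygon(vertices=poly.vertices[hull.vertices].astype(float))
        if poly.signed_area() < 0:
            poly.vertices = poly.vertices[::-1].copy()
        classify_vertices(poly)
        assert all(lbl == APEX for lbl in poly.label)

    def test_star_alternates_apex_base(self):
        poly = ToothPolygon(vertices=_star(6))
        if poly.signed_area() < 0:
            poly.vertices = poly.vertices[::-1].copy()
        classify_vertices(poly)
        apexes = [i for i, lbl in enumerate(poly.label) if lbl == APEX]
        assert len(apexes) == 6
        assert all((a - b) % 2 == 0 for a, b in zip(apexes, apexes[1:]))

    def test_collinear_vertex_is_base(self):
        v = np.array([[0, 0], [0, 5], [0, 10], [10, 10], [10, 0]], float)
        poly = ToothPolygon(vertices=v)
        if poly.signed_area() < 0:
            poly.vertices = poly.vertices[::-1].copy()
        classify_vertices(poly)
        flat = int(np.where((poly.vertices == [0, 5]).all(axis=1))[0][0])
        assert poly.interior_angle[flat] == pytest.approx(180.0)
        assert poly.label[flat] == BASE


class TestBuildTeeth:
    def _labeled_star(self, spikes):
        poly = ToothPolygon(vertices=_star(spikes))
        if poly.signed_area() < 0:
            poly.vertices = poly.vertices[::-1].copy()
        return classify_vertices(poly)

    def test_star_yields_one_tooth_per_spike(self):
        teeth = build_teeth(self._labeled_star(6))
        assert len(teeth) == 6
        for tooth in teeth:
            assert tooth.alternating

    def test_convex_polygon_every_vertex_is_tooth(self):
        from scipy.spatial import ConvexHull

        pts = np.random.default_rng(9).uniform(0, 10, (12, 2))
        hull = ConvexHull(pts)
        poly = ToothPolygon(vertices=pts[hull.vertices].astype(float))
        if poly.signed_area() < 0:
            poly.vertices = poly.vertices[::-1].copy()
        classify_vertices(poly)
        teeth = build_teeth(poly)
        assert len(teeth) == len(poly)
        assert all(not t.alternating for t in teeth)  # neighbors are apexes

    def test_tooth_count_equals_convex_vertex_count(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            poly = ToothPolygon(vertices=_random_star_polygon(rng, int(rng.integers(5, 40))))
            if poly.signed_area() < 0:
                poly.vertices = poly.vertices[::-1].copy()
            classify_vertices(poly)
            teeth = build_teeth(poly)
            assert len(teeth) == (poly.interior_angle < 180).sum()

    def test_no_apex_warns_and_returns_empty(self):
        poly = self._labeled_star(6)
        poly.label = [BASE] * len(poly)
        with pytest.warns(UserWarning):
            assert build_teeth(poly) == []


class TestRefinePolygon:
    def test_displaced_vertices_recover_true_corners(self):
        from leaftooth import LeafSpec, extract_margin, generate_leaf
        from scipy.spatial import cKDTree

        image, gt = generate_leaf(LeafSpec(n_teeth=10, apex_angle=70.0, seed=4))
        contour = extract_margin(image)
        truth = gt.tooth_vertices.reshape(-1, 2)
        tree = cKDTree(contour.points)
        _, idx = tree.query(truth)
        n = contour.length_px
        rng = np.random.default_rng(0)
        displaced = (idx + rng.integers(-4, 5, len(idx))) % n
        corners = [
            CornerPoint(row=int(contour.points[i][0]), col=int(contour.points[i][1]), response=1.0)
            for i in np.unique(displaced)
        ]
        before = np.array([[c.row, c.col] for c in corners], dtype=float)
        d_before, _ = cKDTree(before).query(truth)
        poly = refine_polygon(order_corners(corners, contour), contour)
        d, _ = cKDTree(poly.vertices).query(truth)
        # refinement must undo the displacement down to the ~1 px offset
        # between the traced margin and the vector polygon
        assert d.mean() < 0.6 * d_before.mean()
        assert d.max() < 4.0

    def test_duplicate_cluster_merged(self):
        contour = _circle_contour()
        n = len(contour.points)
        idx = [10, 12, n // 3, n // 2, 3 * n // 4]
        poly = refine_polygon(order_corners(_corners_at(contour, idx), contour), contour)
        assert len(poly) == 4
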