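"""Tooth polygon geometry: corner ordering, interior angles, apex/base labels.

Connecting the detected margin corners in arc order yields a simple polygon
that alternates (ideally) between tooth tips and the indentations flanking
them.  A vertex whose interior angle is smaller than 180 deg is convex and
corresponds to a tooth apex ("top edge"); a reflex vertex (>= 180 deg) sits
in an indentation and corresponds to a tooth base ("bottom edge").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .corners import CornerPoint
from .errors import GeometryError
from .preprocess import MarginContour

log = logging.getLogger(__name__)

__all__ = [
    "ToothPolygon",
    "Tooth",
    "order_corners",
    "refine_polygon",
    "interior_angles",
    "classify_vertices",
    "build_teeth",
]

APEX = "apex"
BASE = "base"


@dataclass
class ToothPolygon:
    """Closed counterclockwise polygon of margin corners.

    ``vertices`` is an (n, 2) float array of (row, col); ``contour_indices``
    gives each vertex's position along the traced margin (when built from a
    contour); ``interior_angle`` and ``label`` are filled by
    :func:`interior_angles` and :func:`classify_vertices`.
    """

    vertices: np.ndarray
    contour_indices: np.ndarray | None = None
    interior_angle: np.ndarray | None = None
    label: list[str] | None = None
    responses: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.vertices)

    def signed_area(self) -> float:
        x = self.vertices[:, 1]
        y = self.vertices[:, 0]
        return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class Tooth:
    """One leaf tooth: apex vertex plus its two polygon-neighbor base vertices.

    ``alternating`` is False when a neighbor of the apex is itself
    apex-labeled (imperfect apex/base alternation in the detected polygon);
    the tooth is still measured, but carries the flag.
    """

    apex: np.ndarray
    base_left: np.ndarray
    base_right: np.ndarray
    index: int
    alternating: bool = True
    degenerate: bool = field(default=False)


def order_corners(corners: list[CornerPoint], contour: MarginContour) -> ToothPolygon:
    """Sort snapped corners by arc position and orient counterclockwise.

    Duplicate contour positions are merged with a warning (keeping the
    stronger response).  Raises :class:`GeometryError` with fewer than 3
    distinct vertices or a degenerate (zero-area) polygon.
    """
    if len(corners) < 3:
        raise GeometryError(f"need >= 3 corners to form a polygon, got {len(corners)}")
    pos_index = {tuple(p): i for i, p in enumerate(map(tuple, contour.points))}
    entries: dict[int, CornerPoint] = {}
    for c in corners:
        key = (c.row, c.col)
        if key not in pos_index:
            raise GeometryError(f"corner {key} does not lie on the contour (snap first)")
        idx = pos_index[key]
        if idx in entries:
            warnings.warn("duplicate corner contour positions merged")
            if c.response <= entries[idx].response:
                continue
        entries[idx] = c
    if len(entries) < 3:
        raise GeometryError("fewer than 3 distinct corners after merging duplicates")
    order = sorted(entries)
    verts = np.array([[entries[i].row, entries[i].col] for i in order], dtype=float)
    resp = np.array([entries[i].response for i in order])
    poly = ToothPolygon(vertices=verts, contour_indices=np.array(order), responses=resp)
    if poly.signed_area() == 0:
        raise GeometryError("degenerate zero-area polygon")
    if poly.signed_area() < 0:
        poly.vertices = poly.vertices[::-1].copy()
        poly.contour_indices = poly.contour_indices[::-1].copy()
        poly.responses = poly.responses[::-1].copy()
    return poly


def _fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through points: (centroid, unit direction)."""
    c = points.mean(axis=0)
    d = points - c
    # principal direction of the 2x2 scatter matrix
    _, vecs = np.linalg.eigh(d.T @ d)
    return c, vecs[:, -1]


def _intersect_lines(c1, d1, c2, d2) -> np.ndarray | None:
    # solve c1 + s*d1 == c2 + t*d2
    A = np.column_stack([d1, -d2])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) < 1e-9:
        return None
    s = np.linalg.solve(A, c2 - c1)[0]
    return c1 + s * d1


def refine_polygon(
    polygon: ToothPolygon,
    contour: MarginContour,
    window: int = 12,
    merge_tol: int = 5,
    gap: int = 3,
    insert_tol: float = 2.5,
) -> ToothPolygon:
    """Vertex cleanup and sub-pixel re-localization of the corner polygon.

    Three passes, all purely geometric:

    1. *Merge*: vertices within ``merge_tol`` arc pixels collapse to the one
       with the larger local bend deviation (corner detectors can report a
       bend twice, and the detector response does not always peak at the
       bend point itself).
    2. *Reflex insertion*: wherever the traced margin dips more than
       ``insert_tol`` px toward the leaf interior from a polygon edge, the
       deepest contour point is inserted as a vertex.  Tooth notches are
       reflex, so a base corner suppressed at detection is recovered here;
       the blade between teeth bulges outward and never triggers insertion.
    3. *Flank-line intersection*: rasterization erodes sharp convex tips
       (the traced margin stops short of the true vertex) and detectors
       localize only to a few pixels.  Each vertex moves to the intersection
       of total-least-squares lines fitted to the contour on either side
       (arc offsets ``gap``..``window``, clipped at the neighbor vertices),
       recovering the true corner even beyond the traced pixels.
       Near-collinear flanks (unstable intersection, or one farther than
       ``window`` px away) leave the vertex at its contour position.

    Requires ``contour_indices`` (vertices on the traced margin).
    """
    if polygon.contour_indices is None:
        raise GeometryError("refine_polygon needs contour-indexed vertices")
    n_pts = contour.length_px
    entries = sorted(
        zip(
            (int(i) for i in polygon.contour_indices),
            polygon.responses if polygon.responses is not None else [0.0] * len(polygon),
        )
    )

    from .corners import contour_bend_deviation

    _dev_cache: dict[int, float] = {}

    def dev(i: int) -> float:
        if i not in _dev_cache:
            _dev_cache[i] = contour_bend_deviation(contour, i)
        return _dev_cache[i]

    def merge(items: list[tuple[int, float]]) -> list[tuple[int, float]]:
        out: list[tuple[int, float]] = []
        for i, r in sorted(items):
            if out and min(i - out[-1][0], n_pts - (i - out[-1][0])) <= merge_tol:
                if (dev(i), r) > (dev(out[-1][0]), out[-1][1]):
                    out[-1] = (i, r)
                continue
            out.append((i, r))
        if len(out) > 1 and (n_pts - out[-1][0] + out[0][0]) <= merge_tol:
            keep = max(out[0], out[-1], key=lambda e: (dev(e[0]), e[1]))
            out = [keep] + out[1:-1] if keep == out[0] else out[1:-1] + [out[-1]]
        return out

    entries = merge(entries)
    if len(entries) < 3:
        raise GeometryError("fewer than 3 vertices after refinement merging")

    # reflex insertion: recover notch corners missing from the vertex set
    pts_f = contour.points.astype(float)
    if insert_tol > 0:
        centroid = pts_f[[i for i, _ in entries]].mean(axis=0)
        for _ in range(4):
            inserted = []
            n = len(entries)
            for i in range(n):
                ia = entries[i][0]
                ib = entries[(i + 1) % n][0]
                span = (ib - ia) % n_pts
                if span < 2 * merge_tol + 2:
                    continue
                arc = (ia + np.arange(1, span)) % n_pts
                a, b = pts_f[ia], pts_f[ib]
                ab = b - a
                nrm = float(np.hypot(*ab))
                if nrm == 0:
                    continue
                d = pts_f[arc] - a
                cross = (d[:, 0] * ab[1] - d[:, 1] * ab[0]) / nrm
                cm = centroid - a
                inward_sign = np.sign(cm[0] * ab[1] - cm[1] * ab[0])
                inward = cross * inward_sign  # positive = toward interior
                j = int(np.argmax(inward))
                if inward[j] > insert_tol:
                    inserted.append((int(arc[j]), 0.0))
            if not inserted:
                break
            entries = merge(entries + inserted)
    n = len(entries)
    idx_arr = np.array([i for i, _ in entries])
    resp_arr = np.array([r for _, r in entries])
    verts = contour.points[idx_arr].astype(float).copy()
    pts = contour.points.astype(float)
    for i in range(n):
        idx = idx_arr[i]
        back_gap = (idx - idx_arr[(i - 1) % n]) % n_pts
        fwd_gap = (idx_arr[(i + 1) % n] - idx) % n_pts
        wb = min(window, back_gap - gap)
        wf = min(window, fwd_gap - gap)
        if wb < gap + 2 or wf < gap + 2:
            continue  # not enough clean flank on one side
        before = pts[(idx - np.arange(gap, wb + 1)) % n_pts]
        after = pts[(idx + np.arange(gap, wf + 1)) % n_pts]
        c1, d1 = _fit_line(before)
        c2, d2 = _fit_line(after)
        cand = _intersect_lines(c1, d1, c2, d2)
        if cand is not None and np.hypot(*(cand - verts[i])) <= window:
            verts[i] = cand
    poly = ToothPolygon(vertices=verts, contour_indices=idx_arr, responses=resp_arr)
    if poly.signed_area() == 0:
        raise GeometryError("degenerate zero-area polygon after refinement")
    if poly.signed_area() < 0:
        poly.vertices = poly.vertices[::-1].copy()
        poly.contour_indices = poly.contour_indices[::-1].copy()
        poly.responses = poly.responses[::-1].copy()
    return poly


def interior_angles(polygon: ToothPolygon) -> np.ndarray:
    """Per-vertex interior angle in degrees, in (0, 360).

    For the counterclockwise polygon, a left turn at a vertex makes it convex
    (angle < 180); a right turn makes it reflex (angle > 180).  Exactly
    collinear neighbors give 180.  Coincident consecutive vertices raise
    :class:`GeometryError`.
    """
    v = polygon.vertices.astype(float)
    if polygon.signed_area() < 0:
        raise GeometryError("interior_angles expects counterclockwise orientation")
    prev = np.roll(v, 1, axis=0)
    nxt = np.roll(v, -1, axis=0)
    a = prev - v
    b = nxt - v
    na = np.hypot(a[:, 0], a[:, 1])
    nb = np.hypot(b[:, 0], b[:, 1])
    if np.any(na == 0) or np.any(nb == 0):
        raise GeometryError("coincident consecutive vertices")
    cosang = np.clip((a * b).sum(axis=1) / (na * nb), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))  # in [0, 180]
    # cross product of incoming edge (v - prev) with outgoing edge (nxt - v),
    # in (x, y) = (col, row): positive z = left turn = convex for CCW polygons
    e_in = v - prev
    e_out = nxt - v
    cross = e_in[:, 1] * e_out[:, 0] - e_in[:, 0] * e_out[:, 1]
    interior = np.where(cross > 0, ang, np.where(cross < 0, 360.0 - ang, 180.0))
    polygon.interior_angle = interior
    return interior


def classify_vertices(polygon: ToothPolygon) -> ToothPolygon:
    """Label each vertex apex (interior angle strictly < 180 deg) or base."""
    if polygon.interior_angle is None:
        interior_angles(polygon)
    polygon.label = [APEX if a < 180.0 else BASE for a in polygon.interior_angle]
    return polygon


def build_teeth(polygon: ToothPolygon) -> list[Tooth]:
    """One Tooth per apex vertex, its bases = the apex's polygon neighbors.

    Neighbors are used regardless of their own label (real detections do not
    always alternate apex/base); non-alternating teeth are flagged.  Teeth
    are ordered along the margin.  No apexes yields an empty list with a
    warning.
    """
    if polygon.label is None:
        classify_vertices(polygon)
    n = len(polygon)
    teeth = []
    for i in range(n):
        if polygon.label[i] != APEX:
            continue
        left = (i - 1) % n
        right = (i + 1) % n
        teeth.append(
            Tooth(
                apex=polygon.vertices[i],
                base_left=polygon.vertices[left],
                base_right=polygon.vertices[right],
                index=i,
                alternating=(polygon.label[left] == BASE and polygon.label[right] == BASE),
            )
        )
    if not teeth:
        warnings.warn("polygon has no apex vertices: no teeth")
    log.info("teeth: %d (of %d polygon vertices)", len(teeth), n)
    return teeth
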