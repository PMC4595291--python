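"""SUSAN corner detection on the leaf margin and 3-sigma corner rejection.

SUSAN compares each pixel's circular-mask neighborhood against the nucleus
brightness: the set of similar pixels is the USAN (Univalue Segment
Assimilating Nucleus).  Its area drops at corners, and the offset of its
centroid from the nucleus points away from the bend.  On a one-pixel margin
curve the USAN area is roughly constant (both curve arms fall inside the
mask wherever the nucleus sits on the curve), so the area alone cannot rank
candidates; the centroid offset, however, grows with the bend sharpness and
vanishes on straight runs.  Detection therefore gates candidates on the
classical area threshold (USAN below g * mask area) and scores them by the
centroid offset, with greedy non-maximum suppression.

Detected corners are snapped to the nearest margin-contour pixel when the
contour is supplied, so downstream polygon construction can order them by
arc position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .outliers import pauta_keep_mask
from .preprocess import MarginContour

log = logging.getLogger(__name__)

__all__ = ["CornerPoint", "PautaStats", "susan_corners", "pauta_filter_corners"]


@dataclass(frozen=True)
class CornerPoint:
    """A detected corner: (row, col) position and detector strength."""

    row: int
    col: int
    response: float


@dataclass(frozen=True)
class PautaStats:
    """Mean/std of corner coordinates used by the 3-sigma filter.

    mu1/sigma1 describe the horizontal (column) coordinates, mu2/sigma2 the
    vertical (row) coordinates; sigmas are population standard deviations.
    """

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float


def contour_bend_deviation(contour: MarginContour, idx: int, window: int = 6) -> float:
    """Bend evidence at contour point ``idx``: mean chord deviation.

    The deviation of the point from the chord joining its two contour
    neighbors w arc-pixels away is averaged over w in {window-2, window,
    window+2}.  On a genuine bend the deviation grows linearly with w, so
    the mean stays large; on a straight or gently curved stretch the
    deviation is dominated by single-pixel staircase peaks that do not
    persist across window sizes, and the mean stays below ~0.7 px.
    """
    pts = contour.points
    n = len(pts)
    p = pts[idx].astype(float)
    devs = []
    for w in (window - 2, window, window + 2):
        if w < 2:
            continue
        a = pts[(idx - w) % n].astype(float)
        b = pts[(idx + w) % n].astype(float)
        ab = b - a
        nrm = float(np.hypot(*ab))
        if nrm == 0:
            devs.append(float(np.hypot(*(p - a))))
            continue
        d = p - a
        devs.append(abs(d[0] * ab[1] - d[1] * ab[0]) / nrm)
    return float(np.mean(devs)) if devs else 0.0


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = (dy * dy + dx * dx) <= radius * radius
    inside[r, r] = False  # nucleus excluded
    return np.column_stack([dy[inside], dx[inside]])


def susan_corners(
    edge_image: np.ndarray,
    mask_radius: float = 3.4,
    brightness_t: float = 27.0,
    geometric_g: float = 0.5,
    centroid_min_dist: float = 0.65,
    nms_radius: float | None = None,
    nms_rel_radius: float | None = None,
    nms_rel_strength: float = 0.75,
    contour: MarginContour | None = None,
    bend_min_dev: float = 1.0,
    bend_window: int = 6,
    convex_min_dist: float = 1.5,
    convex_min_dev: float = 1.3,
) -> list[CornerPoint]:
    """Detect corners of a (binary or grayscale) edge image.

    Parameters mirror the classical detector: ``mask_radius`` (3.4 px gives
    the traditional 37-pixel mask), brightness threshold ``brightness_t`` on
    the 0-255 scale, geometric threshold ``geometric_g`` as a fraction of the
    mask area.  ``centroid_min_dist`` (px) rejects straight-line false
    positives whose USAN centroid stays on the nucleus.

    Non-maximum suppression is two-tier: within ``nms_radius`` (default
    ``mask_radius``) only the strongest candidate survives; within
    ``nms_rel_radius`` (default ``1.4 * mask_radius``) a candidate weaker
    than ``nms_rel_strength`` times an already-accepted stronger one is also
    suppressed.  The relative tier removes the response-plateau tails that a
    sharp bend casts out to roughly the mask diameter, while still allowing
    two genuine bends of comparable strength to coexist at close range.

    When ``contour`` is given, corners are snapped to the nearest contour
    pixel and additionally gated on local bend evidence: the snapped point
    must deviate at least ``bend_min_dev`` px from the chords joining its
    contour neighbors around ``bend_window`` arc pixels away.  This rejects
    detections whose USAN offset comes from a *different* stretch of the
    curve passing through the mask (e.g. the opposite flank of a narrow
    tooth) while the curve is locally straight at the nucleus.  Candidates
    bending *away* from the leaf interior (convex side) face the stricter
    ``convex_min_dist`` / ``convex_min_dev`` thresholds: every convex tooth
    vertex is a sharp apex with strong evidence, whereas rasterization
    artifacts on the gently convex blade arc are weak — and genuinely weak
    reflex corners (shallow tooth bases) are recovered later by reflex
    insertion during polygon refinement, so asymmetric gating loses nothing.

    Returns corners sorted by (row, col), each carrying the centroid-offset
    strength; empty input yields an empty list.
    """
    img = np.asarray(edge_image)
    if img.dtype == bool or img.max() <= 1:
        img = img.astype(float) * 255.0
    else:
        img = img.astype(float)
    if nms_radius is None:
        nms_radius = mask_radius
    if nms_rel_radius is None:
        nms_rel_radius = 1.4 * mask_radius

    nz = np.argwhere(img > 0)
    if len(nz) == 0:
        return []
    r = int(np.ceil(mask_radius))
    r0, c0 = np.maximum(nz.min(axis=0) - r, 0)
    r1, c1 = np.minimum(nz.max(axis=0) + r + 1, img.shape)
    win = img[r0:r1, c0:c1]
    pad = np.pad(win, r, mode="constant")

    offsets = _disk_offsets(mask_radius)
    n_max = len(offsets)
    h, w = win.shape
    levels = np.unique(win)
    if len(levels) == 2:
        # binary fast path: similarity is 1 for equal levels and a constant
        # s0 for differing levels, so USAN and centroid sums are disc
        # convolutions of the indicator image
        from scipy.signal import fftconvolve

        s0 = float(np.exp(-(((levels[1] - levels[0]) / brightness_t) ** 6)))
        rr = int(np.ceil(mask_radius))
        ker = np.zeros((2 * rr + 1, 2 * rr + 1))
        ker_y = np.zeros_like(ker)
        ker_x = np.zeros_like(ker)
        for dy, dx in offsets:
            # convolution flips the kernel; store at (-dy, -dx)
            ker[rr - dy, rr - dx] = 1.0
            ker_y[rr - dy, rr - dx] = dy
            ker_x[rr - dy, rr - dx] = dx
        E = (win == levels[1]).astype(float)  # 1 on the curve
        ones = np.ones_like(E)
        conv_e = fftconvolve(E, ker, mode="same")
        conv_y = fftconvolve(E, ker_y, mode="same")
        conv_x = fftconvolve(E, ker_x, mode="same")
        count = fftconvolve(ones, ker, mode="same")  # in-frame disc sizes
        county = fftconvolve(ones, ker_y, mode="same")
        countx = fftconvolve(ones, ker_x, mode="same")
        # values below are only consulted at on-curve nuclei (high-level pixels)
        usan = conv_e + s0 * (count - conv_e)
        cy = conv_y + s0 * (county - conv_y)
        cx = conv_x + s0 * (countx - conv_x)
    else:
        usan = np.zeros_like(win)
        cy = np.zeros_like(win)
        cx = np.zeros_like(win)
        for dy, dx in offsets:
            shifted = pad[r + dy : r + dy + h, r + dx : r + dx + w]
            sim = np.exp(-(((shifted - win) / brightness_t) ** 6))
            usan += sim
            cy += dy * sim
            cx += dx * sim
    response = geometric_g * n_max - usan
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.hypot(cy / usan, cx / usan)
    on_curve = win > 0
    cand = on_curve & (response > 0) & (dist >= centroid_min_dist)
    # nuclei whose mask leaves the image frame are unreliable: exclude a
    # border band of one mask radius (classical practice)
    H, W = img.shape
    gy = np.arange(r0, r1)[:, None]
    gx = np.arange(c0, c1)[None, :]
    cand &= (gy >= r) & (gy < H - r) & (gx >= r) & (gx < W - r)
    ys, xs = np.nonzero(cand)
    if len(ys) == 0:
        return []
    scores = dist[ys, xs]

    # greedy two-tier non-maximum suppression by centroid-offset strength
    order = np.lexsort((xs, ys, -scores))
    kept: list[tuple[int, int, float]] = []
    accepted = np.empty((0, 2))
    acc_scores = np.empty(0)
    for i in order:
        p = np.array([ys[i], xs[i]], dtype=float)
        if len(kept):
            d = np.hypot(*(accepted - p).T)
            if np.min(d) <= nms_radius:
                continue
            near = d <= nms_rel_radius
            if near.any() and scores[i] < nms_rel_strength * acc_scores[near].max():
                continue
        kept.append((ys[i] + r0, xs[i] + c0, float(scores[i])))
        accepted = np.vstack([accepted, p])
        acc_scores = np.append(acc_scores, scores[i])

    if contour is not None and len(kept):
        tree = cKDTree(contour.points)
        cpts = contour.points.astype(float)
        centroid = cpts.mean(axis=0)
        n_c = len(cpts)
        snapped = []
        seen = set()
        for y, x, s in kept:
            _, idx = tree.query([y, x])
            idx = int(idx)
            dev = contour_bend_deviation(contour, idx, window=bend_window)
            if dev < bend_min_dev:
                continue
            a = cpts[(idx - bend_window) % n_c]
            b = cpts[(idx + bend_window) % n_c]
            ab = b - a
            side = ab[1] * (cpts[idx] - a)[0] - ab[0] * (cpts[idx] - a)[1]
            inward = ab[1] * (centroid - a)[0] - ab[0] * (centroid - a)[1]
            if side * inward < 0:  # bends away from the interior: convex
                if s < convex_min_dist or dev < convex_min_dev:
                    continue
            pos = tuple(contour.points[idx])
            if pos in seen:
                continue
            seen.add(pos)
            snapped.append(CornerPoint(row=int(pos[0]), col=int(pos[1]), response=s))
        kept_pts = snapped
    else:
        kept_pts = [CornerPoint(row=int(y), col=int(x), response=s) for y, x, s in kept]
    kept_pts.sort(key=lambda c: (c.row, c.col))
    log.info("susan: %d corners", len(kept_pts))
    return kept_pts


def pauta_filter_corners(
    corners: list[CornerPoint],
) -> tuple[list[CornerPoint], list[CornerPoint], PautaStats | None]:
    """Remove corners whose coordinates deviate > 3 sigma from the corner cloud.

    A corner is abnormal iff its column deviates from mu1 by more than
    3*sigma1 *or* its row deviates from mu2 by more than 3*sigma2 (strict
    inequalities, population sigma, single pass).  With fewer than 3 corners
    the filter is skipped with a warning and stats are undefined (None).
    """
    if len(corners) < 3:
        warnings.warn("fewer than 3 corners: PauTa filter skipped")
        return list(corners), [], None
    cols = np.array([c.col for c in corners], dtype=float)
    rows = np.array([c.row for c in corners], dtype=float)
    keep_c, mu1, s1 = pauta_keep_mask(cols)
    keep_r, mu2, s2 = pauta_keep_mask(rows)
    keep = keep_c & keep_r
    kept = [c for c, k in zip(corners, keep) if k]
    removed = [c for c, k in zip(corners, keep) if not k]
    log.info("pauta corners: removed %d of %d", len(removed), len(corners))
    return kept, removed, PautaStats(mu1=mu1, sigma1=s1, mu2=mu2, sigma2=s2)
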