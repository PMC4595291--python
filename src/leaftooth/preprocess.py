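"""Leaf image pre-processing: photograph -> ordered one-pixel margin contour.

The chain is: grayscale conversion, thresholding (Otsu by default, local mean
adaptive optionally), interior hole filling (which erases venation and other
non-margin structure from the silhouette), Roberts-cross edge detection,
morphological thinning and finally an ordered trace of the largest closed
boundary.  Coordinates are (row, col), 0-based, row increasing downward.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import roberts, threshold_local, threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, skeletonize

from .errors import DegenerateInputError, ExtractionError, InputError

log = logging.getLogger(__name__)

__all__ = [
    "MarginContour",
    "to_grayscale",
    "binarize",
    "fill_interior",
    "edge_detect",
    "thin_and_trace",
    "extract_margin",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class MarginContour:
    """Ordered, closed, one-pixel-wide leaf margin.

    ``points`` is an (n, 2) integer array of (row, col); consecutive points
    are 8-neighbors and, for a closed contour, the last point is an
    8-neighbor of the first.  ``length_px`` is the number of margin pixels.
    """

    points: np.ndarray
    closed: bool = True

    @property
    def length_px(self) -> int:
        return len(self.points)

    def as_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.points[:, 0], self.points[:, 1]] = True
        return m


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a color image to intensity with the standard luminance weights.

    Grayscale input is passed through unchanged.  A 4-channel (RGBA) image has
    its alpha channel dropped with a warning.  Integer inputs stay integer
    (rounded), so a pure red (255, 0, 0) pixel maps to 76 on the 0-255 scale.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 4:
        warnings.warn("alpha channel dropped")
        img = img[:, :, :3]
    if img.ndim == 3 and img.shape[2] == 3:
        gray = img.astype(float) @ _LUMA
        if np.issubdtype(img.dtype, np.integer):
            return np.round(gray).astype(img.dtype)
        return gray
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0]
    raise InputError(f"unsupported image shape {img.shape}; expected 1, 3 or 4 channels")


def _largest_interior_component_area(mask: np.ndarray) -> int:
    """Area of the largest connected component not touching the image border."""
    lab = label(mask, connectivity=2)
    if lab.max() == 0:
        return 0
    border = np.unique(np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
    areas = np.bincount(lab.ravel())
    areas[0] = 0
    areas[border] = 0
    return int(areas.max())


def binarize(
    gray: np.ndarray,
    method: str = "otsu",
    window: int = 35,
    offset: float = 0.0,
    foreground: str = "auto",
) -> np.ndarray:
    """Threshold a grayscale image into a boolean leaf mask.

    ``method`` is 'otsu' (global, parameter-free) or 'local_adaptive'
    (mean filter of size ``window`` minus ``offset``).  Foreground polarity:
    'auto' picks the side whose largest non-border-touching component is
    bigger (a photographed leaf is centered while the background touches the
    frame); 'dark'/'light' force it.
    """
    g = np.asarray(gray, dtype=float)
    if g.ndim != 2:
        raise InputError("binarize expects a single-channel image")
    if g.min() == g.max():
        raise DegenerateInputError("constant image: no threshold separates foreground")
    if method == "otsu":
        thr = threshold_otsu(g)
        dark = g <= thr
    elif method == "local_adaptive":
        thr = threshold_local(g, block_size=window | 1, method="mean", offset=offset)
        dark = g <= thr
    else:
        raise InputError(f"unknown threshold method {method!r}")
    if foreground == "dark":
        return dark
    if foreground == "light":
        return ~dark
    if foreground != "auto":
        raise InputError(f"unknown foreground polarity {foreground!r}")
    if _largest_interior_component_area(~dark) > _largest_interior_component_area(dark):
        return ~dark
    return dark


def fill_interior(mask: np.ndarray) -> np.ndarray:
    """Fill interior holes (venation artifacts) and keep the largest component.

    Every background region not connected to the image border becomes
    foreground; then only the largest foreground component is retained, so a
    single-leaf assumption is enforced.
    """
    m = np.asarray(mask, dtype=bool)
    filled = ndimage.binary_fill_holes(m)
    lab = label(filled, connectivity=2)
    if lab.max() == 0:
        return filled
    areas = np.bincount(lab.ravel())
    areas[0] = 0
    return lab == int(areas.argmax())


def edge_detect(mask: np.ndarray) -> np.ndarray:
    """Roberts-cross silhouette edge: pixels with nonzero gradient magnitude."""
    m = np.asarray(mask, dtype=float)
    edges = roberts(m) > 1e-12
    if not edges.any():
        warnings.warn("no edges found (uniform mask)")
    return edges


_NEIGH = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
)


def _prune_spurs(skel: np.ndarray) -> np.ndarray:
    """Iteratively delete endpoints (pixels with fewer than 2 neighbors)."""
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    s = skel.copy()
    while True:
        nb = ndimage.convolve(s.astype(int), kernel, mode="constant")
        spurs = s & (nb < 2)
        if not spurs.any():
            return s
        s = s & ~spurs


def _simplify_curve(skel: np.ndarray) -> np.ndarray:
    """Remove redundant pixels so the curve approaches uniform degree 2.

    Thinning can leave small staircase clusters where a pixel has 3+
    neighbors that remain mutually connected without it; such pixels are
    deleted one at a time (deterministic scan order) until none remain.
    """
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    s = skel.copy()
    changed = True
    while changed:
        changed = False
        nb = ndimage.convolve(s.astype(int), kernel, mode="constant")
        for y, x in np.argwhere(s & (nb >= 3)):
            block = s[y - 1 : y + 2, x - 1 : x + 2].copy()
            if block.shape != (3, 3):
                continue
            block[1, 1] = False
            if block.sum() < 3:  # degree may have dropped since the sweep began
                continue
            lab = label(block, connectivity=2)
            if lab.max() != 1:
                continue
            # removal must not strand a neighbor below degree 2
            s[y, x] = False
            ok = True
            for dy, dx in _NEIGH:
                ny, nx = y + dy, x + dx
                if 0 <= ny < s.shape[0] and 0 <= nx < s.shape[1] and s[ny, nx]:
                    deg = s[max(ny - 1, 0) : ny + 2, max(nx - 1, 0) : nx + 2].sum() - 1
                    if deg < 2:
                        ok = False
                        break
            if ok:
                changed = True
            else:
                s[y, x] = True
    return s


def _trace_cycle(component: np.ndarray) -> np.ndarray | None:
    """Walk an 8-connected closed curve into an ordered point sequence.

    Depth-first chain following with backtracking: at each pixel the walk
    prefers the unvisited neighbor that continues the current direction;
    when it dead-ends it backtracks and tries alternatives (thinning can
    leave isolated degree-3 pixels).  Accepts the first cycle back to the
    start that covers at least 90% of the component's pixels.
    """
    pts = np.argwhere(component)
    n_px = len(pts)
    if n_px < 4:
        return None
    pixset = {tuple(p) for p in pts}
    start = tuple(pts[np.lexsort((pts[:, 1], pts[:, 0]))][0])

    def candidates(cur, prev):
        nbrs = [
            (cur[0] + dr, cur[1] + dc)
            for dr, dc in _NEIGH
            if (cur[0] + dr, cur[1] + dc) in pixset
        ]
        cand = [p for p in nbrs if p not in visited]
        if prev is not None:
            cand.sort(key=lambda p: (-abs(p[0] - prev[0]) - abs(p[1] - prev[1]), p))
        return cand, nbrs

    path = [start]
    visited = {start}
    cand0, _ = candidates(start, None)
    stack = [iter(cand0)]
    budget = 20 * n_px
    while stack and budget > 0:
        budget -= 1
        cur = path[-1]
        prev = path[-2] if len(path) > 1 else None
        advanced = False
        for nxt in stack[-1]:
            path.append(nxt)
            visited.add(nxt)
            cand, _ = candidates(nxt, cur)
            if not cand:
                _, nbrs = candidates(nxt, cur)
                if start in nbrs and len(path) >= 0.9 * n_px:
                    return np.array(path)
                # dead end: undo immediately
                path.pop()
                visited.discard(nxt)
                continue
            stack.append(iter(cand))
            advanced = True
            break
        if not advanced:
            if len(path) == 1:
                return None
            stack.pop()
            visited.discard(path.pop())
    return None


def _orient_ccw(points: np.ndarray) -> np.ndarray:
    x = points[:, 1].astype(float)
    y = points[:, 0].astype(float)
    area2 = float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return points if area2 > 0 else points[::-1].copy()


def thin_and_trace(edges: np.ndarray) -> MarginContour:
    """Thin the edge set to unit width and trace the largest closed contour."""
    e = np.asarray(edges, dtype=bool)
    if not e.any():
        raise ExtractionError("thin_and_trace", "empty edge image")
    skel = _simplify_curve(_prune_spurs(skeletonize(e)))
    lab = label(skel, connectivity=2)
    if lab.max() == 0:
        raise ExtractionError("thin_and_trace", "no closed contour after thinning")
    areas = np.bincount(lab.ravel())
    areas[0] = 0
    for comp_id in np.argsort(areas)[::-1]:
        if areas[comp_id] == 0:
            break
        path = _trace_cycle(lab == comp_id)
        if path is not None:
            if len(path) < areas[comp_id]:
                log.debug("trace skipped %d of %d pixels", areas[comp_id] - len(path), areas[comp_id])
            return MarginContour(points=_orient_ccw(path), closed=True)
    raise ExtractionError("thin_and_trace", "no closed contour found")


def extract_margin(
    image: np.ndarray,
    method: str = "otsu",
    window: int = 35,
    offset: float = 0.0,
    foreground: str = "auto",
    venation_removal: str = "fill",
) -> MarginContour:
    """Full pre-processing chain: photograph to ordered margin contour.

    ``venation_removal`` selects how non-margin edges are suppressed:
    'fill' (default) fills interior holes of the binary mask before edge
    detection; 'dilate' instead dilates the mask with a radius-2 disk and
    relies on thinning, mirroring a dilation-based cleanup.
    """
    stage = "to_grayscale"
    try:
        gray = to_grayscale(image)
        stage = "binarize"
        mask = binarize(gray, method=method, window=window, offset=offset, foreground=foreground)
        stage = "fill_interior"
        if venation_removal == "fill":
            mask = fill_interior(mask)
        elif venation_removal == "dilate":
            mask = ndimage.binary_dilation(mask, structure=disk(2).astype(bool))
            mask = fill_interior(mask)
        else:
            raise InputError(f"unknown venation_removal {venation_removal!r}")
        # a light opening removes single-pixel nubs that would skeletonize
        # into tip loops; blunts sharp tips by at most one pixel
        mask = fill_interior(ndimage.binary_opening(mask))  # 3x3 cross
        stage = "edge_detect"
        edges = edge_detect(mask)
        stage = "thin_and_trace"
        contour = thin_and_trace(edges)
    except ExtractionError:
        raise
    except (InputError, DegenerateInputError) as exc:
        raise ExtractionError(stage, str(exc)) from exc
    log.info("margin extracted: %d px", contour.length_px)
    return contour
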