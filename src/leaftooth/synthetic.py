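"""Synthetic toothed-leaf silhouettes with exact vector ground truth.

Real serrate leaves present a smooth blade outline decorated with small
triangular marginal teeth.  The generator emulates exactly that: an elliptic
or ovate base curve carries ``n_teeth`` isoceles triangular teeth, each
defined by two base vertices on the curve and an apex displaced outward along
the chord normal.  The apex height is chosen from the requested apex angle so
that the angle at the apex is *exactly* ``apex_angle`` in the vector polygon;
the tooth base/height ratio is therefore exactly ``2*tan(apex_angle/2)``.

Boundary noise is applied in vector space (Gaussian jitter of the tooth
vertices; the blade between teeth stays smooth at pixel scale, as on a real
leaf) before rasterization, so the ground truth of the jittered polygon
remains exact.  Rasterization is hard binary (dark leaf on white background,
no anti-aliasing): tests built on these images probe geometry, not
photometry.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw
from skimage.draw import polygon_perimeter

from .errors import InputError

__all__ = ["LeafSpec", "GroundTruth", "generate_leaf", "generate_dataset"]


@dataclass(frozen=True)
class LeafSpec:
    """Parameters of one synthetic leaf silhouette.

    n_teeth           number of marginal teeth (>= 3)
    apex_angle        tooth apex angle in degrees, strictly inside (0, 180)
    tooth_height_frac tooth height as a fraction of the local blade radius
    base_shape        'ellipse' or 'ovate' (egg-like, broader toward one end)
    aspect            blade elongation (length/width of the base curve)
    size_px           raster is size_px x size_px (>= 128)
    noise_sd          Gaussian vertex jitter in pixels (>= 0)
    seed              RNG seed controlling the jitter
    """

    n_teeth: int = 12
    apex_angle: float = 60.0
    tooth_height_frac: float = 0.10
    base_shape: str = "ellipse"
    aspect: float = 1.35
    size_px: int = 768
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_teeth < 3:
            raise InputError(f"n_teeth must be >= 3, got {self.n_teeth}")
        if not 0.0 < self.apex_angle < 180.0:
            raise InputError(f"apex_angle must lie in (0, 180), got {self.apex_angle}")
        if self.size_px < 128:
            raise InputError(f"size_px must be >= 128, got {self.size_px}")
        if self.noise_sd < 0:
            raise InputError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.tooth_height_frac <= 0:
            raise InputError("tooth_height_frac must be positive")
        if self.base_shape not in ("ellipse", "ovate"):
            raise InputError(f"unknown base_shape {self.base_shape!r}")


@dataclass
class GroundTruth:
    """Exact vector-space truth for one generated leaf.

    Angles/ratios are reported both for the ideal construction ("ideal_")
    and recomputed from the jittered polygon that was actually rasterized.
    ``perimeter_px`` counts the pixels of the rasterized polygon outline,
    which is the natural reference for a traced one-pixel margin;
    ``perimeter_geom`` is the Euclidean polygon length.
    """

    tooth_count: int
    ideal_apex_angle_deg: float
    ideal_obliqueness: float
    mean_apex_angle_deg: float
    mean_obliqueness: float
    apex_angles_deg: np.ndarray
    obliquenesses: np.ndarray
    tooth_vertices: np.ndarray  # (n_teeth, 3, 2) rows of (base1, apex, base2) as (row, col)
    perimeter_geom: float
    perimeter_px: int
    polygon: np.ndarray = field(repr=False)  # (n_points, 2) jittered (row, col)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=1)


def _base_curve(spec: LeafSpec, t: np.ndarray) -> np.ndarray:
    """Points of the base (toothless) blade outline as (row, col), shape (m, 2)."""
    half = spec.size_px / 2.0
    ov = 0.18 if spec.base_shape == "ovate" else 0.0
    # keep the whole toothed, jittered outline inside the frame
    sr = (half - 8.0 - 3.0 * spec.noise_sd) / ((1.0 + spec.tooth_height_frac) * (1.0 + ov))
    sr = min(sr, 0.45 * spec.size_px)
    sc = sr / spec.aspect
    scale = 1.0 + ov * np.sin(t)
    rows = half + sr * np.cos(t) * scale
    cols = half + sc * np.sin(t) * scale
    return np.column_stack([rows, cols])


def _chord_halfwidth(spec: LeafSpec, t0: float, target_chord: float) -> float:
    """Half-angle delta with |P(t0+delta) - P(t0-delta)| == target_chord."""
    def chord(delta):
        p = _base_curve(spec, np.array([t0 - delta, t0 + delta]))
        return float(np.hypot(*(p[1] - p[0])))

    lo, hi = 1e-4, np.pi / spec.n_teeth
    if chord(hi) < target_chord:
        return hi  # clamped; density check below will reject if too tight
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if chord(mid) < target_chord:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _triangle_measures(b1: np.ndarray, apex: np.ndarray, b2: np.ndarray) -> tuple[float, float]:
    """(apex angle in degrees, base/height obliqueness) of one tooth triangle."""
    a = b1 - apex
    b = b2 - apex
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    d1 = float(np.linalg.norm(b2 - b1))
    u, v = b2 - b1, apex - b1
    area = 0.5 * abs(float(u[0] * v[1] - u[1] * v[0]))
    return ang, d1 * d1 / (2.0 * area)


def generate_leaf(spec: LeafSpec) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize one toothed leaf; returns (uint8 image, GroundTruth).

    The image is ``size_px`` square, white (255) background, dark (30) leaf.
    Deterministic: the same spec (including seed) yields a bit-identical image.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_teeth
    center = np.array([spec.size_px / 2.0, spec.size_px / 2.0])
    t_apex = 2.0 * np.pi * (np.arange(n) + 0.5) / n
    half_angle_rad = np.radians(spec.apex_angle / 2.0)

    # per-tooth base half-width in parameter space
    deltas = np.empty(n)
    for i, t0 in enumerate(t_apex):
        p0 = _base_curve(spec, np.array([t0]))[0]
        r_local = float(np.hypot(*(p0 - center)))
        h = spec.tooth_height_frac * r_local
        chord = 2.0 * h * np.tan(half_angle_rad)
        deltas[i] = _chord_halfwidth(spec, t0, chord)

    gap = 2.0 * np.pi / n
    for i in range(n):
        if deltas[i] + deltas[(i + 1) % n] > 0.92 * gap:
            raise InputError(
                "teeth too dense to remain simple: reduce n_teeth, apex_angle "
                "or tooth_height_frac"
            )

    # assemble polygon: per tooth (base1, apex, base2) then the arc to the next base1
    points: list[np.ndarray] = []
    apex_idx: list[int] = []
    base_idx: list[tuple[int, int]] = []
    for i in range(n):
        t0 = t_apex[i]
        b1, b2 = _base_curve(spec, np.array([t0 - deltas[i], t0 + deltas[i]]))
        chord_vec = b2 - b1
        chord_len = float(np.hypot(*chord_vec))
        h = (chord_len / 2.0) / np.tan(half_angle_rad)  # exact apex angle
        normal = np.array([-chord_vec[1], chord_vec[0]]) / chord_len
        mid = 0.5 * (b1 + b2)
        if np.dot(normal, mid - center) < 0:
            normal = -normal
        apex = mid + h * normal
        base_idx.append((len(points), len(points) + 2))
        points.append(b1)
        apex_idx.append(len(points))
        points.append(apex)
        points.append(b2)
        # arc to the next tooth's first base vertex
        t_start = t0 + deltas[i]
        t_end = t_apex[(i + 1) % n] - deltas[(i + 1) % n]
        if i == n - 1:
            t_end += 2.0 * np.pi
        r_local = float(np.hypot(*(mid - center)))
        n_arc = max(2, int(np.ceil((t_end - t_start) * r_local / 2.0)))
        t_arc = np.linspace(t_start, t_end, n_arc + 1)[1:-1]
        for p in _base_curve(spec, t_arc):
            points.append(p)

    poly = np.array(points)
    if spec.noise_sd > 0:
        # jitter the tooth vertices only: real margin noise perturbs the
        # teeth; the blade between teeth stays smooth at pixel scale
        jitter_rows = sorted(
            set(apex_idx) | {i for pair in base_idx for i in pair}
        )
        poly[jitter_rows] += rng.normal(0.0, spec.noise_sd, size=(len(jitter_rows), 2))

    angles = np.empty(n)
    obliq = np.empty(n)
    verts = np.empty((n, 3, 2))
    for i in range(n):
        i1, i2 = base_idx[i]
        b1, apex, b2 = poly[i1], poly[apex_idx[i]], poly[i2]
        angles[i], obliq[i] = _triangle_measures(b1, apex, b2)
        verts[i] = [b1, apex, b2]

    closed = np.vstack([poly, poly[:1]])
    perimeter_geom = float(np.sum(np.hypot(*(np.diff(closed, axis=0).T))))
    rr, cc = polygon_perimeter(poly[:, 0], poly[:, 1], shape=(spec.size_px, spec.size_px))
    perimeter_px = int(len(np.unique(rr * spec.size_px + cc)))

    pil = Image.new("L", (spec.size_px, spec.size_px), 255)
    ImageDraw.Draw(pil).polygon([(c, r) for r, c in poly], fill=30)
    image = np.asarray(pil, dtype=np.uint8).copy()

    gt = GroundTruth(
        tooth_count=n,
        ideal_apex_angle_deg=float(spec.apex_angle),
        ideal_obliqueness=float(2.0 * np.tan(half_angle_rad)),
        mean_apex_angle_deg=float(angles.mean()),
        mean_obliqueness=float(obliq.mean()),
        apex_angles_deg=angles,
        obliquenesses=obliq,
        tooth_vertices=verts,
        perimeter_geom=perimeter_geom,
        perimeter_px=perimeter_px,
        polygon=poly,
    )
    return image, gt


# within-species jitter fractions applied by generate_dataset
DEFAULT_PARAM_JITTER = {"n_teeth": 0.08, "apex_angle": 0.06, "tooth_height_frac": 0.10}


def generate_dataset(
    species_specs: list[tuple[LeafSpec, str, int]],
    seed: int = 0,
    out_dir: str | Path | None = None,
    param_jitter: dict | None = None,
) -> list[dict]:
    """Generate a labeled multi-species image set with within-species variation.

    Each record is ``{"image", "species", "ground_truth", "spec", "path"}``
    (``path`` only when ``out_dir`` is given, in which case PNGs, per-image
    ground-truth JSON and a ``manifest.csv`` of (path, species) are written).
    Per-image parameter jitter (relative sd per parameter, see
    ``DEFAULT_PARAM_JITTER``) emulates individual variation within a species.
    """
    if param_jitter is None:
        param_jitter = DEFAULT_PARAM_JITTER
    records = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(sum(c for _, _, c in species_specs) * 2)
    k = 0
    for spec, label, count in species_specs:
        for _ in range(count):
            rng = np.random.default_rng(int(child_seeds[k]) % (2**31))
            for _attempt in range(20):
                n_teeth = max(3, int(round(spec.n_teeth * (1.0 + rng.normal(0, param_jitter["n_teeth"])))))
                apex = float(np.clip(spec.apex_angle * (1.0 + rng.normal(0, param_jitter["apex_angle"])), 5.0, 175.0))
                hfrac = float(spec.tooth_height_frac * np.clip(1.0 + rng.normal(0, param_jitter["tooth_height_frac"]), 0.5, 1.5))
                leaf_spec = dataclasses.replace(
                    spec, n_teeth=n_teeth, apex_angle=apex, tooth_height_frac=hfrac,
                    seed=int(child_seeds[k + 1]) % (2**31),
                )
                try:
                    image, gt = generate_leaf(leaf_spec)
                    break
                except InputError:  # jittered teeth too dense: redraw
                    continue
            else:
                raise InputError(
                    f"could not draw a feasible leaf for species {label!r}; "
                    "base spec is too close to the density limit"
                )
            records.append({"image": image, "species": label, "ground_truth": gt, "spec": leaf_spec})
            k += 2

    if out_dir is not None:
        import imageio.v3 as iio
        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, rec in enumerate(records):
            name = f"leaf_{i:04d}_{rec['species']}"
            path = out / f"{name}.png"
            iio.imwrite(path, rec["image"])
            (out / f"{name}.gt.json").write_text(rec["ground_truth"].to_json())
            rec["path"] = str(path)
            rows.append({"path": str(path), "species": rec["species"]})
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return records
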