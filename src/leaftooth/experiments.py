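"""Reproducible study harnesses: recovery sweeps and the species benchmark.

These functions define the package's standard validation experiments on the
synthetic generator: tooth-count recovery across counts, apex-angle and
obliqueness recovery across angles, and the repeated stratified-split
species identification benchmark with its permuted-label control.  Every
randomness source derives from the single ``seed`` argument.

Within a sweep condition, the controlled parameter is held fixed while the
nuisance parameters (apex angle or tooth size, blade shape and elongation)
are jittered per leaf, emulating individual variation.  At large apex
angles the tooth height is drawn below the geometric density limit
(adjacent teeth must not overlap).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .classifier import EvaluationReport, evaluate
from .errors import InputError
from .pipeline import LeafToothFeatureExtractor
from .synthetic import LeafSpec, generate_dataset, generate_leaf

__all__ = [
    "SPECIES_BENCHMARK_SPECS",
    "tooth_count_recovery",
    "angle_recovery",
    "species_benchmark",
    "random_simple_polygon",
]


def _segments_cross(p1, p2, p3, p4) -> bool:
    def cr(u, v):
        return u[0] * v[1] - u[1] * v[0]

    d1 = cr(p4 - p3, p1 - p3)
    d2 = cr(p4 - p3, p2 - p3)
    d3 = cr(p2 - p1, p3 - p1)
    d4 = cr(p2 - p1, p4 - p1)
    return d1 * d2 < 0 and d3 * d4 < 0


def _is_simple(v: np.ndarray) -> bool:
    n = len(v)
    for i in range(n):
        for j in range(i + 1, n):
            if j - i <= 1 or (i == 0 and j == n - 1):
                continue
            if _segments_cross(v[i], v[(i + 1) % n], v[j], v[(j + 1) % n]):
                return False
    return True


def random_simple_polygon(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random simple polygon with ``n`` vertices, (n, 2) float array.

    Random points polygonized by sorting around their centroid; the result
    is verified non-self-intersecting (and resampled in the rare degenerate
    case), so angle-sum identities can be asserted exactly.
    """
    for _ in range(100):
        pts = rng.uniform(-10.0, 10.0, (n, 2))
        c = pts.mean(axis=0)
        ang = np.arctan2(pts[:, 0] - c[0], pts[:, 1] - c[1])
        if len(np.unique(np.round(ang, 9))) < n:
            continue
        v = pts[np.argsort(ang)]
        if _is_simple(v):
            return v
    raise RuntimeError("could not draw a simple polygon")

# the three-species benchmark conditions: distinct tooth count / apex angle /
# tooth size regimes with within-species parameter jitter and half-pixel
# boundary noise
SPECIES_BENCHMARK_SPECS = [
    (LeafSpec(n_teeth=10, apex_angle=55.0, tooth_height_frac=0.13, noise_sd=0.5), "species_a"),
    (LeafSpec(n_teeth=18, apex_angle=85.0, tooth_height_frac=0.11, noise_sd=0.5, base_shape="ovate"), "species_b"),
    (LeafSpec(n_teeth=26, apex_angle=70.0, tooth_height_frac=0.09, noise_sd=0.5), "species_c"),
]


@dataclass
class RecoveryResult:
    """Per-leaf outcomes of a recovery sweep."""

    condition: np.ndarray  # controlled parameter value per leaf
    truth: np.ndarray  # generator ground truth per leaf
    measured: np.ndarray  # extracted value per leaf


def _count_sweep_leaf(T: int, rng: np.random.Generator):
    """One leaf with exactly T teeth; nuisance draws redrawn if infeasible."""
    for _ in range(50):
        spec = LeafSpec(
            n_teeth=T,
            apex_angle=float(np.clip(60.0 * (1 + rng.normal(0, 0.06)), 35.0, 140.0)),
            tooth_height_frac=float(np.clip(0.10 * (1 + rng.normal(0, 0.10)), 0.07, 0.13)),
            base_shape="ovate" if rng.random() < 0.5 else "ellipse",
            aspect=float(1.2 + 0.3 * rng.random()),
            seed=int(rng.integers(2**31)),
        )
        try:
            return generate_leaf(spec)
        except InputError:  # teeth too dense for this nuisance draw
            continue
    raise InputError(f"no feasible nuisance draw found for {T} teeth")


def tooth_count_recovery(
    tooth_counts=(8, 12, 16, 24, 30),
    leaves_per_count: int = 10,
    seed: int = 0,
    extractor: LeafToothFeatureExtractor | None = None,
) -> RecoveryResult:
    """Extract leaf_num from noise-free leaves of known tooth count.

    Per count, ``leaves_per_count`` distinct leaves are drawn by jittering
    the nuisance shape parameters.  Returns per-leaf true and extracted
    tooth counts.
    """
    extractor = extractor or LeafToothFeatureExtractor()
    rng = np.random.default_rng(seed)
    cond, truth, measured = [], [], []
    for T in tooth_counts:
        images = [_count_sweep_leaf(T, rng)[0] for _ in range(leaves_per_count)]
        X = extractor.transform(images)
        cond.extend([T] * leaves_per_count)
        truth.extend([T] * leaves_per_count)
        measured.extend(X[:, 0].tolist())
    return RecoveryResult(np.array(cond), np.array(truth), np.array(measured))


def angle_recovery(
    apex_angles=(40.0, 60.0, 90.0, 120.0),
    leaves_per_angle: int = 3,
    seed: int = 0,
    extractor: LeafToothFeatureExtractor | None = None,
) -> tuple[RecoveryResult, RecoveryResult]:
    """Extract sharpness and obliqueness from leaves of known apex angle.

    Returns (sharpness result, obliqueness result); truth values are the
    generator's per-leaf realized mean apex angle and base/height ratio.
    The tooth height is drawn within the density-feasible band for 12 teeth
    at the widest angle.
    """
    extractor = extractor or LeafToothFeatureExtractor()
    rng = np.random.default_rng(seed)
    cond, sh_true, sh_meas, ob_true, ob_meas = [], [], [], [], []
    for theta in apex_angles:
        for k in range(leaves_per_angle):
            spec = LeafSpec(
                n_teeth=12,
                apex_angle=float(theta),
                tooth_height_frac=float(rng.uniform(0.075, 0.092)),
                base_shape="ovate" if k % 2 else "ellipse",
                seed=int(rng.integers(2**31)),
            )
            image, gt = generate_leaf(spec)
            X = extractor.transform([image])
            cond.append(theta)
            sh_true.append(gt.mean_apex_angle_deg)
            sh_meas.append(X[0, 2])
            ob_true.append(gt.mean_obliqueness)
            ob_meas.append(X[0, 3])
    cond = np.array(cond)
    sharp = RecoveryResult(cond, np.array(sh_true), np.array(sh_meas))
    obliq = RecoveryResult(cond.copy(), np.array(ob_true), np.array(ob_meas))
    return sharp, obliq


def species_benchmark(
    seed: int = 0,
    images_per_species: int = 40,
    alpha: float = 0.01,
    n_runs: int = 5,
    permuted_runs: int = 10,
    extractor: LeafToothFeatureExtractor | None = None,
    features: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[EvaluationReport, EvaluationReport, np.ndarray, np.ndarray]:
    """Three-species identification benchmark with permuted-label control.

    Generates the benchmark image set (seeded), extracts the four features,
    runs the repeated stratified 50/50 protocol, and repeats it with labels
    randomly permuted (the chance-level control).  Pre-extracted
    ``features`` = (X, y) can be supplied to skip the image stage.
    Returns (report, permuted_report, X, y).
    """
    ss = np.random.SeedSequence(seed)
    s_data, s_eval, s_perm, s_perm_eval = (int(s) % (2**31) for s in ss.generate_state(4))
    if features is None:
        extractor = extractor or LeafToothFeatureExtractor()
        specs = [(spec, label, images_per_species) for spec, label in SPECIES_BENCHMARK_SPECS]
        records = generate_dataset(specs, seed=s_data)
        X = extractor.transform([r["image"] for r in records])
        y = np.array([r["species"] for r in records])
    else:
        X, y = features
    report = evaluate(X, y, alpha=alpha, n_runs=n_runs, seed=s_eval)
    y_perm = np.random.default_rng(s_perm).permutation(y)
    permuted = evaluate(X, y_perm, alpha=alpha, n_runs=permuted_runs, seed=s_perm_eval)
    return report, permuted, X, y
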