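"""The four leaf-tooth features and their normalization.

Per leaf the feature vector is

* leaf_num        — number of detected teeth,
* leaf_rate       — teeth per margin pixel (leaf_num / margin length),
* leaf_sharpness  — 3-sigma-filtered mean of the per-tooth apex angles
                    Ta_i = arccos of the normalized inner product of the two
                    apex-to-base vectors, in degrees,
* leaf_obliqueness— 3-sigma-filtered mean of the per-tooth base/height
                    ratios Te_i = |d1| / |d2| = |d1|^2 / (2 S), where |d1| is
                    the distance between the two base vertices and S the
                    tooth triangle area.

Degenerate (collinear) teeth are excluded from the angle/ratio pools but
still counted in leaf_num: the count reflects detection, the measures
require valid geometry.  Min-max scaling to [0, 1] is learned on training
features and applied with clipping to test features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateToothError
from .geometry import Tooth
from .outliers import pauta_keep_mask
from .preprocess import MarginContour

log = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "MeasurePautaStats",
    "FeatureScaler",
    "tooth_sharpness",
    "tooth_obliqueness",
    "pauta_filter_measures",
    "compute_feature_vector",
    "fit_scaler",
    "apply_scaler",
]

FEATURE_NAMES = ("leaf_num", "leaf_rate", "leaf_sharpness", "leaf_obliqueness")


@dataclass
class FeatureVector:
    """The 4-tuple of leaf-tooth features for one leaf image.

    ``leaf_sharpness``/``leaf_obliqueness`` are NaN for a leaf with no
    measurable teeth; such a vector is flagged unclassifiable.
    """

    leaf_num: int
    leaf_rate: float
    leaf_sharpness: float
    leaf_obliqueness: float

    @property
    def unclassifiable(self) -> bool:
        return self.leaf_num == 0 or np.isnan(self.leaf_sharpness) or np.isnan(self.leaf_obliqueness)

    def as_array(self) -> np.ndarray:
        return np.array([self.leaf_num, self.leaf_rate, self.leaf_sharpness, self.leaf_obliqueness])


@dataclass(frozen=True)
class MeasurePautaStats:
    """Mean/std (population) of the per-tooth measures before filtering:
    mu3/sigma3 for the sharpness angles, mu4/sigma4 for the obliqueness."""

    mu3: float
    sigma3: float
    mu4: float
    sigma4: float


def tooth_sharpness(tooth: Tooth) -> float:
    """Apex angle of one tooth in degrees, in [0, 180].

    Angle between the vectors a = base_left - apex and b = base_right - apex,
    from the arccosine of their normalized inner product; invariant to rigid
    motions and uniform scaling.  A zero-length vector raises
    :class:`DegenerateToothError`; exactly collinear vertices return 0/180
    but mark the tooth degenerate.
    """
    a = np.asarray(tooth.base_left, dtype=float) - tooth.apex
    b = np.asarray(tooth.base_right, dtype=float) - tooth.apex
    na, nb = np.hypot(*a), np.hypot(*b)
    if na == 0 or nb == 0:
        raise DegenerateToothError("apex coincides with a base vertex")
    ang = float(np.degrees(np.arccos(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))))
    if ang in (0.0, 180.0):
        tooth.degenerate = True
    return ang


def tooth_obliqueness(tooth: Tooth) -> float:
    """Base/height ratio Te = |d1|^2 / (2 S) of the tooth triangle.

    |d1| is the base length (distance between the two base vertices) and S
    the triangle area (shoelace); the identity |d1|^2/(2S) = |d1|/|d2| holds
    because S = |d1| |d2| / 2 with |d2| the height.  Zero area raises
    :class:`DegenerateToothError`.
    """
    b1 = np.asarray(tooth.base_left, dtype=float)
    b2 = np.asarray(tooth.base_right, dtype=float)
    apex = np.asarray(tooth.apex, dtype=float)
    d1 = float(np.hypot(*(b2 - b1)))
    u, v = b2 - b1, apex - b1
    area = 0.5 * abs(float(u[0] * v[1] - u[1] * v[0]))
    if area == 0:
        tooth.degenerate = True
        raise DegenerateToothError("collinear tooth vertices (zero area)")
    return d1 * d1 / (2.0 * area)


def pauta_filter_measures(
    values: np.ndarray | list[float],
) -> tuple[float, np.ndarray, np.ndarray, tuple[float, float]]:
    """3-sigma filter a pool of per-tooth measures; returns the re-computed mean.

    Returns (filtered_mean, kept_values, removed_values, (mu, sigma)).
    Population sigma, strict > 3 sigma removal, single pass; the filtered
    mean is the mean of the survivors.  At least one value always survives.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("pauta_filter_measures needs at least one value")
    keep, mu, sigma = pauta_keep_mask(v)
    kept = v[keep]
    removed = v[~keep]
    return float(kept.mean()), kept, removed, (mu, sigma)


def compute_feature_vector(
    teeth: list[Tooth], contour: MarginContour, pauta: bool = True
) -> tuple[FeatureVector, MeasurePautaStats | None]:
    """Aggregate per-tooth measures into the 4-dimensional leaf feature vector.

    Degenerate teeth are excluded from the sharpness/obliqueness pools but
    counted in leaf_num.  With ``pauta`` False the unfiltered means are used.
    Zero teeth yields (0, 0, NaN, NaN), flagged unclassifiable.
    """
    leaf_num = len(teeth)
    leaf_rate = leaf_num / contour.length_px if contour.length_px else 0.0
    ta, te = [], []
    for tooth in teeth:
        try:
            angle = tooth_sharpness(tooth)
            ratio = tooth_obliqueness(tooth)
        except DegenerateToothError:
            continue
        if tooth.degenerate:
            continue
        ta.append(angle)
        te.append(ratio)
    if not ta:
        fv = FeatureVector(leaf_num, leaf_rate, float("nan"), float("nan"))
        return fv, None
    if pauta:
        sharp, _, rm_ta, (mu3, s3) = pauta_filter_measures(ta)
        obli, _, rm_te, (mu4, s4) = pauta_filter_measures(te)
        log.info(
            "features: %d teeth, pauta removed %d angles / %d ratios",
            leaf_num, len(rm_ta), len(rm_te),
        )
    else:
        sharp, obli = float(np.mean(ta)), float(np.mean(te))
        mu3, s3 = sharp, float(np.std(ta))
        mu4, s4 = obli, float(np.std(te))
    fv = FeatureVector(leaf_num, leaf_rate, sharp, obli)
    return fv, MeasurePautaStats(mu3=mu3, sigma3=s3, mu4=mu4, sigma4=s4)


@dataclass
class FeatureScaler:
    """Per-dimension min-max scaler to [0, 1] learned from training features.

    A constant training dimension maps every value to 0.5; test values
    outside the training range are clipped into [0, 1].
    """

    min_: np.ndarray
    max_: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        span = self.max_ - self.min_
        out = np.empty_like(X)
        const = span == 0
        out[:, const] = 0.5
        out[:, ~const] = (X[:, ~const] - self.min_[~const]) / span[~const]
        return np.clip(out, 0.0, 1.0)


def fit_scaler(train_features: np.ndarray) -> FeatureScaler:
    """Learn per-dimension min/max from an (n, d) training feature matrix."""
    X = np.atleast_2d(np.asarray(train_features, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("fit_scaler needs at least 2 training vectors")
    return FeatureScaler(min_=X.min(axis=0), max_=X.max(axis=0))


def apply_scaler(scaler: FeatureScaler, v: np.ndarray) -> np.ndarray:
    """Scale feature vector(s) with a trained scaler (clipped to [0, 1])."""
    out = scaler.transform(v)
    return out[0] if np.asarray(v).ndim == 1 else out
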