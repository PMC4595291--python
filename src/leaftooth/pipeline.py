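"""End-to-end pipeline: leaf image -> margin -> corners -> teeth -> features.

``PipelineConfig`` collects every tunable of the chain and serializes to a
plain-text ``key = value`` file.  ``extract_features`` runs the chain on one
image; :class:`LeafToothFeatureExtractor` wraps it as a (stateless)
scikit-learn transformer mapping a sequence of images to an (n, 4) feature
matrix.

The SUSAN mask radius defaults to 13 px here (rather than the classical
3.4 px of :func:`leaftooth.corners.susan_corners`): on a one-pixel margin
curve the corner evidence is the USAN-centroid offset, whose magnitude grows
with the mask arm length, so a larger mask separates genuine tooth bends
from rasterization staircase jitter (offset ~0.7 px regardless of radius)
far more reliably at the default 768 px image scale.  Scale it with image
resolution: the mask must stay below the tooth flank length.  Detected
corners are then re-localized geometrically (``refine_window``), so the
coarse localization of a wide mask costs nothing.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .corners import pauta_filter_corners, susan_corners
from .errors import ExtractionError, GeometryError, InputError
from .features import FeatureVector, compute_feature_vector
from .geometry import build_teeth, classify_vertices, order_corners, refine_polygon
from .preprocess import extract_margin

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "extract_features", "LeafToothFeatureExtractor"]


@dataclass
class PipelineConfig:
    """All tunables of the image -> feature-vector chain.

    threshold_method   'otsu' or 'local_adaptive'
    local_window       local threshold window (px, odd)
    local_offset       local threshold offset
    foreground         'auto', 'dark' or 'light'
    venation_removal   'fill' or 'dilate'
    mask_radius        SUSAN circular mask radius (px)
    brightness_t       SUSAN brightness threshold (0-255)
    geometric_g        SUSAN geometric threshold (fraction of mask area)
    centroid_min_dist  minimum USAN-centroid offset for a corner (px)
    nms_radius         absolute non-maximum suppression radius (px; 0 = mask_radius)
    nms_rel_radius     relative suppression radius (px; 0 = 1.4 * mask_radius)
    nms_rel_strength   relative suppression strength ratio
    refine_window      vertex re-localization search window (arc px; 0 = off)
    pauta_corners      apply the 3-sigma corner filter
    pauta_measures     apply the 3-sigma filter to per-tooth measures
    alpha              lasso penalty used at classification time
    seed               seed forwarded to downstream randomness
    debug_dir          if set, write per-image debug artifacts there
    """

    threshold_method: str = "otsu"
    local_window: int = 35
    local_offset: float = 0.0
    foreground: str = "auto"
    venation_removal: str = "fill"
    mask_radius: float = 13.0
    brightness_t: float = 27.0
    geometric_g: float = 0.5
    centroid_min_dist: float = 1.0
    nms_radius: float = 12.0
    nms_rel_radius: float = 18.0
    nms_rel_strength: float = 0.75
    refine_window: int = 12
    pauta_corners: bool = True
    pauta_measures: bool = True
    alpha: float = 0.01
    seed: int = 0
    debug_dir: str = ""

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InputError(f"{path}:{ln}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise InputError(f"{path}:{ln}: unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def extract_features(
    image: np.ndarray, config: PipelineConfig | None = None
) -> tuple[FeatureVector, dict]:
    """Run the full chain on one image.

    Returns (feature vector, diagnostics).  Diagnostics carry the contour,
    corner sets, polygon and teeth together with per-stage counts; stage
    failures raise :class:`ExtractionError` tagged with the stage name.
    A margin on which no usable polygon can be formed yields a zero-tooth
    (unclassifiable) feature vector rather than an error.
    """
    cfg = config or PipelineConfig()
    contour = extract_margin(
        image,
        method=cfg.threshold_method,
        window=cfg.local_window,
        offset=cfg.local_offset,
        foreground=cfg.foreground,
        venation_removal=cfg.venation_removal,
    )
    edge_mask = contour.as_mask(np.asarray(image).shape[:2])
    corners = susan_corners(
        edge_mask,
        mask_radius=cfg.mask_radius,
        brightness_t=cfg.brightness_t,
        geometric_g=cfg.geometric_g,
        centroid_min_dist=cfg.centroid_min_dist,
        nms_radius=cfg.nms_radius or None,
        nms_rel_radius=cfg.nms_rel_radius or None,
        nms_rel_strength=cfg.nms_rel_strength,
        contour=contour,
    )
    removed = []
    stats = None
    if cfg.pauta_corners:
        corners, removed, stats = pauta_filter_corners(corners)
    diagnostics = {
        "contour": contour,
        "corners": corners,
        "corners_removed": removed,
        "corner_stats": stats,
        "margin_px": contour.length_px,
    }
    try:
        polygon = order_corners(corners, contour)
        if cfg.refine_window > 0:
            polygon = refine_polygon(polygon, contour, window=cfg.refine_window)
        polygon = classify_vertices(polygon)
        teeth = build_teeth(polygon)
    except GeometryError as exc:
        log.warning("no tooth polygon: %s", exc)
        polygon, teeth = None, []
    diagnostics["polygon"] = polygon
    diagnostics["teeth"] = teeth
    fv, measure_stats = compute_feature_vector(teeth, contour, pauta=cfg.pauta_measures)
    diagnostics["measure_stats"] = measure_stats
    log.info(
        "image: margin=%d px, corners=%d (-%d), teeth=%d, features=(%d, %.4g, %.4g, %.4g)",
        contour.length_px, len(corners), len(removed), fv.leaf_num,
        fv.leaf_num, fv.leaf_rate, fv.leaf_sharpness, fv.leaf_obliqueness,
    )
    return fv, diagnostics


class LeafToothFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer: sequence of leaf images -> (n, 4) tooth-feature matrix.

    Stateless (``fit`` is a no-op); parameters mirror
    :class:`PipelineConfig`.  Rows for unclassifiable leaves contain NaN in
    the sharpness/obliqueness columns.
    """

    def __init__(
        self,
        threshold_method: str = "otsu",
        foreground: str = "auto",
        venation_removal: str = "fill",
        mask_radius: float = 13.0,
        brightness_t: float = 27.0,
        geometric_g: float = 0.5,
        centroid_min_dist: float = 1.0,
        nms_radius: float = 12.0,
        nms_rel_radius: float = 18.0,
        nms_rel_strength: float = 0.75,
        refine_window: int = 12,
        pauta_corners: bool = True,
        pauta_measures: bool = True,
    ):
        self.threshold_method = threshold_method
        self.foreground = foreground
        self.venation_removal = venation_removal
        self.mask_radius = mask_radius
        self.brightness_t = brightness_t
        self.geometric_g = geometric_g
        self.centroid_min_dist = centroid_min_dist
        self.nms_radius = nms_radius
        self.nms_rel_radius = nms_rel_radius
        self.nms_rel_strength = nms_rel_strength
        self.refine_window = refine_window
        self.pauta_corners = pauta_corners
        self.pauta_measures = pauta_measures

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            threshold_method=self.threshold_method,
            foreground=self.foreground,
            venation_removal=self.venation_removal,
            mask_radius=self.mask_radius,
            brightness_t=self.brightness_t,
            geometric_g=self.geometric_g,
            centroid_min_dist=self.centroid_min_dist,
            nms_radius=self.nms_radius,
            nms_rel_radius=self.nms_rel_radius,
            nms_rel_strength=self.nms_rel_strength,
            refine_window=self.refine_window,
            pauta_corners=self.pauta_corners,
            pauta_measures=self.pauta_measures,
        )

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        rows = []
        for img in X:
            fv, _ = extract_features(np.asarray(img), cfg)
            rows.append(fv.as_array())
        return np.array(rows)
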