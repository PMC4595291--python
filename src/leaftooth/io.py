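"""File formats: images in, feature tables (CSV) and models (JSON) round-trip."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import Dictionary, SparseRepresentationClassifier
from .errors import InputError, ModelFormatError
from .features import FeatureScaler

__all__ = [
    "read_image",
    "write_feature_table",
    "read_feature_table",
    "save_model",
    "load_model",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ["image_id", "species", "leaf_num", "leaf_rate", "leaf_sharpness", "leaf_obliqueness"]
_NUMERIC = FEATURE_COLUMNS[2:]
MODEL_SCHEMA_VERSION = 1


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG/TIFF image; RGBA alpha is dropped with a warning."""
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise InputError(f"image not found: {path}")
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        warnings.warn(f"{path.name}: alpha channel dropped")
        img = img[:, :, :3]
    return img


def write_feature_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table CSV with the canonical 6-column header."""
    missing = [c for c in FEATURE_COLUMNS if c not in rows.columns]
    if missing:
        raise InputError(f"feature table missing column(s): {', '.join(missing)}")
    rows.loc[:, FEATURE_COLUMNS].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature table CSV (lossless numeric round-trip)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"feature table not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise InputError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s): {', '.join(missing)}")
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, after header
            raise InputError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = coerced
    return df


def save_model(model: SparseRepresentationClassifier, path: str | Path) -> None:
    """Serialize a fitted classifier (scaler, atoms, labels, alpha) to JSON."""
    if not hasattr(model, "dictionary_"):
        raise InputError("model is not fitted")
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "alpha": model.alpha,
        "tol": model.tol,
        "max_iter": model.max_iter,
        "classes": [str(c) for c in model.classes_],
        "atom_labels": [str(c) for c in model.dictionary_.atom_labels],
        "atoms": model.dictionary_.atoms.tolist(),  # row-major (d, n)
        "scaler_min": model.scaler_.min_.tolist(),
        "scaler_max": model.scaler_.max_.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> SparseRepresentationClassifier:
    """Load a classifier saved by :func:`save_model`; checks the schema version."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"model file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelFormatError(
            f"unsupported model schema version {version!r} (expected {MODEL_SCHEMA_VERSION})"
        )
    clf = SparseRepresentationClassifier(
        alpha=payload["alpha"], tol=payload["tol"], max_iter=payload["max_iter"]
    )
    atoms = np.array(payload["atoms"], dtype=float)
    labels = np.array(payload["atom_labels"])
    clf.dictionary_ = Dictionary(atoms=atoms, atom_labels=labels, classes=np.array(payload["classes"]))
    clf.classes_ = clf.dictionary_.classes
    clf.scaler_ = FeatureScaler(
        min_=np.array(payload["scaler_min"], dtype=float),
        max_=np.array(payload["scaler_max"], dtype=float),
    )
    clf.n_features_in_ = atoms.shape[0]
    return clf
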