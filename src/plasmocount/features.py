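"""HSV feature extraction around detected particles.

Each detection is summarized by three numbers: the mean hue, saturation and
value of the 5x5-pixel region of interest (ROI) centred on the integer peak.
HSV separates chromaticity (H, S) from brightness (V), which makes the
colour identity of a plasmonic nanoparticle robust to illumination changes.
Hue is angular (wrap-around at pure red), so ROI hues are averaged
circularly (vector mean of the hue angle); saturation and value are averaged
arithmetically. Features are z-scored with statistics fitted on the training
split only, and the fitted normalizer travels with the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import color as _skcolor

from .detect import DetectionSet
from .errors import InvalidInputError
from .io import ProjectedImage

__all__ = [
    "FEATURE_COLUMNS",
    "rgb_to_hsv",
    "extract_roi_features",
    "NormalizerParams",
    "fit_normalizer",
    "apply_normalizer",
]

FEATURE_COLUMNS = ("h", "s", "v")
_EPS_SCALE = 1e-12


def rgb_to_hsv(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Standard hexcone RGB -> HSV transform for unit-range scalars.

    Achromatic inputs (max == min) get h = 0, s = 0 by convention.
    """
    rgb = np.array([r, g, b], dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise InvalidInputError(f"RGB components must lie in [0, 1]; got {(r, g, b)}")
    h, s, v = _skcolor.rgb2hsv(rgb.reshape(1, 1, 3))[0, 0]
    return float(h), float(s), float(v)


def _circular_mean_hue(hues: np.ndarray) -> float:
    """Vector mean of hue angles; falls back to 0 when the resultant vanishes."""
    ang = 2.0 * np.pi * hues
    x, y = np.cos(ang).mean(), np.sin(ang).mean()
    if np.hypot(x, y) < 1e-12:
        return 0.0
    h = float(np.arctan2(y, x) / (2.0 * np.pi) % 1.0)
    return 0.0 if h >= 1.0 else h  # tiny negative angles must not round to 1.0


def extract_roi_features(
    image: ProjectedImage,
    detections: DetectionSet | np.ndarray,
    roi_size: int = 5,
) -> pd.DataFrame:
    """Mean HSV of the ``roi_size`` x ``roi_size`` ROI around each detection.

    Integer pixels are scaled to [0, 1] by the image bit depth before colour
    conversion. Returns a DataFrame with columns
    ``detection_id, row, col, h, s, v``.
    """
    if roi_size < 1 or roi_size % 2 == 0:
        raise InvalidInputError("roi_size must be an odd positive integer")
    half = roi_size // 2
    centres = (
        detections.positions()
        if isinstance(detections, DetectionSet)
        else np.asarray(detections, dtype=int).reshape(-1, 2)
    )
    rows, cols = image.data.shape[:2]
    bad = [
        i
        for i, (r, c) in enumerate(centres)
        if r - half < 0 or c - half < 0 or r + half >= rows or c + half >= cols
    ]
    if bad:
        raise InvalidInputError(
            f"ROI overruns image border for detection_id(s) {bad}"
        )

    scaled = image.data.astype(np.float64) / image.max_value
    hsv = _skcolor.rgb2hsv(scaled)
    records = []
    for i, (r, c) in enumerate(centres):
        roi = hsv[r - half : r + half + 1, c - half : c + half + 1]
        records.append(
            {
                "detection_id": i,
                "row": int(r),
                "col": int(c),
                "h": _circular_mean_hue(roi[..., 0].ravel()),
                "s": float(roi[..., 1].mean()),
                "v": float(roi[..., 2].mean()),
            }
        )
    return pd.DataFrame(
        records, columns=["detection_id", "row", "col", "h", "s", "v"]
    )


@dataclass(frozen=True)
class NormalizerParams:
    """Per-feature z-scoring statistics estimated on the training set."""

    location: tuple[float, ...]
    scale: tuple[float, ...]
    columns: tuple[str, ...] = FEATURE_COLUMNS

    def to_dict(self) -> dict:
        return {
            "location": list(self.location),
            "scale": list(self.scale),
            "columns": list(self.columns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizerParams":
        return cls(
            location=tuple(float(x) for x in d["location"]),
            scale=tuple(float(x) for x in d["scale"]),
            columns=tuple(d["columns"]),
        )


def fit_normalizer(features: pd.DataFrame, columns=FEATURE_COLUMNS) -> NormalizerParams:
    """Per-feature mean and standard deviation over the given (training) rows.

    A constant column gets its scale clamped to a tiny epsilon so that its
    normalized values are exactly zero rather than NaN.
    """
    if len(features) == 0:
        raise InvalidInputError("cannot fit a normalizer on an empty table")
    x = features[list(columns)].to_numpy(dtype=float)
    location = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale = np.where(scale > _EPS_SCALE, scale, _EPS_SCALE)
    return NormalizerParams(
        location=tuple(map(float, location)),
        scale=tuple(map(float, scale)),
        columns=tuple(columns),
    )


def apply_normalizer(features: pd.DataFrame, params: NormalizerParams) -> pd.DataFrame:
    """Z-score feature columns; all other columns pass through unchanged."""
    missing = [c for c in params.columns if c not in features.columns]
    if missing:
        raise InvalidInputError(f"feature table lacks column(s) {missing}")
    out = features.copy()
    for j, c in enumerate(params.columns):
        x = out[c].to_numpy(dtype=float)
        centred = x - params.location[j]
        # a column clamped to the epsilon scale is constant: map it to zero
        if params.scale[j] <= _EPS_SCALE:
            out[c] = np.where(np.abs(centred) < 1e-9, 0.0, centred / params.scale[j])
        else:
            out[c] = centred / params.scale[j]
    return out
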