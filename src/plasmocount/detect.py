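"""Local-maxima detection of diffraction-limited nanoparticle spots.

Detection runs on the luminance (per-pixel mean of R, G, B) so that no
colour class is privileged. The local background — pedestal plus diffuse
membrane-scatter clutter, estimated with a median filter much wider than a
diffraction-limited spot — is subtracted and the result optionally
Gaussian-smoothed before candidate maxima are collected. A candidate must
exceed both

* ``threshold_rel`` times the robust maximum (99.9th percentile of the
  background-subtracted luminance, resistant to single hot pixels), and
* ``noise_floor_k`` times a robust estimate (scaled MAD) of the smoothed
  background noise,

and maxima closer than ``min_distance_px`` (Chebyshev) are suppressed
greedily in order of decreasing intensity, ties broken by (row, col).
A flat plateau of equal maxima therefore yields its lexicographically
smallest pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidInputError
from .io import ProjectedImage

__all__ = [
    "DetectionParams",
    "DetectionSet",
    "detect_particles",
    "detection_recall_precision",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the spot detector.

    Defaults suit diffraction-limited spots a few pixels across:
    ``min_distance_px`` matches the 5x5 feature ROI so ROIs of distinct
    particles cannot coincide.
    """

    smoothing_sigma_px: float = 1.0
    min_distance_px: int = 5
    threshold_rel: float = 0.1
    border_margin_px: int = 2
    noise_floor_k: float = 7.0
    background_window_px: int = 15

    def __post_init__(self) -> None:
        if self.smoothing_sigma_px < 0:
            raise InvalidInputError("smoothing_sigma_px must be >= 0")
        if self.min_distance_px < 1:
            raise InvalidInputError("min_distance_px must be a positive integer")
        if not (0.0 < self.threshold_rel < 1.0):
            raise InvalidInputError("threshold_rel must lie in (0, 1)")
        if self.border_margin_px < 0:
            raise InvalidInputError("border_margin_px must be >= 0")
        if self.noise_floor_k < 0:
            raise InvalidInputError("noise_floor_k must be >= 0")
        if self.background_window_px < 3 or self.background_window_px % 2 == 0:
            raise InvalidInputError("background_window_px must be an odd integer >= 3")


@dataclass
class DetectionSet:
    """Integer particle centres with their peak (smoothed, background-
    subtracted) luminance, sorted by descending intensity."""

    centres: pd.DataFrame  # columns: row, col, peak_intensity
    image_shape: tuple[int, int]
    params: DetectionParams = field(default_factory=DetectionParams)

    def __len__(self) -> int:
        return len(self.centres)

    def positions(self) -> np.ndarray:
        """(n, 2) integer array of (row, col) centres."""
        return self.centres[["row", "col"]].to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        self.centres.to_csv(path, index=False)

    def params_dict(self) -> dict:
        return asdict(self.params)


def _luminance(image: ProjectedImage) -> np.ndarray:
    return image.data.astype(np.float64).mean(axis=-1)


def detect_particles(image: ProjectedImage, params: DetectionParams | None = None) -> DetectionSet:
    """Locate every bright spot in a projected darkfield image."""
    if params is None:
        params = DetectionParams()
    rows, cols = image.data.shape[:2]
    if rows < 2 * params.border_margin_px or cols < 2 * params.border_margin_px:
        raise InvalidInputError(
            f"image of shape {(rows, cols)} smaller than twice the border margin "
            f"({params.border_margin_px} px)"
        )

    lum = _luminance(image)
    # local background (pedestal + diffuse clutter); the window dwarfs a
    # diffraction-limited spot, so spots do not bias their own baseline
    w = params.background_window_px
    lum = lum - ndimage.median_filter(lum, size=w, mode="nearest")
    if params.smoothing_sigma_px > 0:
        lum = ndimage.gaussian_filter(lum, sigma=params.smoothing_sigma_px)

    robust_max = float(np.percentile(lum, 99.9))
    # scaled MAD of the smoothed field ~ sigma of the background noise
    noise_sigma = 1.4826 * float(np.median(np.abs(lum - np.median(lum))))
    threshold = max(params.threshold_rel * robust_max, params.noise_floor_k * noise_sigma)

    # local maxima: strictly >= every 8-neighbour (plateaus keep all pixels,
    # greedy suppression below then selects the lexicographically smallest)
    footprint = np.ones((3, 3), dtype=bool)
    is_max = lum >= ndimage.maximum_filter(lum, footprint=footprint, mode="nearest")
    is_max &= lum > threshold

    m = params.border_margin_px
    if m > 0:
        border = np.zeros_like(is_max)
        border[m : rows - m, m : cols - m] = True
        is_max &= border

    cand_r, cand_c = np.nonzero(is_max)
    cand_v = lum[cand_r, cand_c]
    order = np.lexsort((cand_c, cand_r, -cand_v))
    cand_r, cand_c, cand_v = cand_r[order], cand_c[order], cand_v[order]

    # greedy Chebyshev non-maximum suppression on an occupancy grid
    keep_r: list[int] = []
    keep_c: list[int] = []
    keep_v: list[float] = []
    occupied = np.zeros((rows, cols), dtype=bool)
    d = params.min_distance_px
    for r, c, v in zip(cand_r, cand_c, cand_v):
        if occupied[r, c]:
            continue
        keep_r.append(int(r))
        keep_c.append(int(c))
        keep_v.append(float(v))
        r0, r1 = max(0, r - d + 1), min(rows, r + d)
        c0, c1 = max(0, c - d + 1), min(cols, c + d)
        occupied[r0:r1, c0:c1] = True

    centres = pd.DataFrame({"row": keep_r, "col": keep_c, "peak_intensity": keep_v})
    return DetectionSet(centres=centres, image_shape=(rows, cols), params=params)


def detection_recall_precision(
    detections: DetectionSet | np.ndarray,
    truth: np.ndarray | pd.DataFrame,
    match_radius_px: float,
) -> dict:
    """Greedy nearest-neighbour matching of detections against ground truth.

    Pairs are formed in order of increasing Euclidean distance; each truth
    point and each detection is used at most once and pairs farther than
    ``match_radius_px`` are excluded. Returns a dict with ``recall``,
    ``precision`` and the matched index pairs.
    """
    if match_radius_px <= 0:
        raise InvalidInputError("match_radius_px must be > 0")
    det = detections.positions() if isinstance(detections, DetectionSet) else np.asarray(detections, dtype=float)
    if isinstance(truth, pd.DataFrame):
        truth = truth[["row", "col"]].to_numpy(dtype=float)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    det = det.reshape(-1, 2).astype(float)

    n_det, n_truth = len(det), len(truth)
    if n_det == 0 and n_truth == 0:
        return {"recall": 1.0, "precision": 1.0, "matched_pairs": []}
    if n_det == 0 or n_truth == 0:
        return {"recall": 0.0, "precision": 0.0, "matched_pairs": []}

    diff = det[:, None, :] - truth[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    pairs = [
        (dist[i, j], i, j)
        for i in range(n_det)
        for j in range(n_truth)
        if dist[i, j] <= match_radius_px
    ]
    pairs.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_det or j in used_truth:
            continue
        used_det.add(i)
        used_truth.add(j)
        matched.append((i, j))
    return {
        "recall": len(matched) / n_truth,
        "precision": len(matched) / n_det,
        "matched_pairs": matched,
    }
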