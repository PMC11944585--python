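"""Locate culture plates in photographs and crop them for classification.

The detection pipeline mirrors the classical gradient/Hough approach: a
Gaussian blur suppresses sensor noise, first-derivative (Sobel) gradients are
computed separately on each RGB channel, the per-channel magnitudes are
combined and min-max normalized into an edge-emphasis map, and a circle
Hough transform votes in (center, radius) space for the plate rim.  The
best-fitting circle is then cropped to a square and resized for the CNN.

Parameters follow the conventional circle-transform interface: ``dp`` (inverse
accumulator resolution ratio), ``minDist`` (minimum distance between detected
centers), ``param1`` (edge threshold feeding the accumulator), ``param2``
(accumulator vote threshold), and the radius search bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import circle_perimeter, disk
from skimage.transform import hough_circle, resize

__all__ = [
    "HoughParams",
    "DetectedCircle",
    "default_hough_params",
    "compute_edge_map",
    "detect_plates",
    "select_best_circle",
    "crop_circle",
    "annotate_detections",
]

DEFAULT_BLUR_KERNEL = 9
DEFAULT_BLUR_SIGMA = 2.0


@dataclass(frozen=True)
class HoughParams:
    dp: float = 1.0
    minDist: float = 128.0
    param1: float = 100.0
    param2: float = 50.0
    minRadius: int = 64
    maxRadius: int = 256

    def __post_init__(self) -> None:
        if self.dp < 1:
            raise ValueError("dp must be >= 1")
        if self.minDist <= 0:
            raise ValueError("minDist must be > 0")
        if self.param1 <= 0 or self.param2 <= 0:
            raise ValueError("param1 and param2 must be > 0")
        if not 0 <= self.minRadius <= self.maxRadius:
            raise ValueError("need 0 <= minRadius <= maxRadius")


@dataclass(frozen=True)
class DetectedCircle:
    """A plate hypothesis: center (cx, cy), radius r, accumulator votes."""

    cx: float
    cy: float
    r: float
    score: float

    def __post_init__(self) -> None:
        if self.r < 0 or self.score < 0:
            raise ValueError("radius and score must be non-negative")


def default_hough_params(image_shape: tuple[int, ...]) -> HoughParams:
    """Defaults scaled to the image: search radii in [min_dim/8, min_dim/2]."""
    min_dim = min(image_shape[:2])
    return HoughParams(
        dp=1.0,
        minDist=min_dim / 4.0,
        param1=100.0,
        param2=50.0,
        minRadius=max(1, min_dim // 8),
        maxRadius=min_dim // 2,
    )


def compute_edge_map(
    image: np.ndarray,
    blur_kernel: int = DEFAULT_BLUR_KERNEL,
    blur_sigma: float = DEFAULT_BLUR_SIGMA,
) -> np.ndarray:
    """Blur, per-channel Sobel gradients, channel combination, normalization.

    Each RGB channel is Gaussian-blurred (kernel size ``blur_kernel`` px,
    truncated accordingly), horizontal and vertical Sobel derivatives are
    taken per channel, and the three per-channel magnitudes are combined by
    root-sum-of-squares so that an edge present in any single channel still
    responds.  The result is min-max normalized to [0, 255] (float); a
    constant image maps to all zeros.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    if blur_kernel < 1 or blur_kernel % 2 == 0:
        raise ValueError(f"blur_kernel must be odd and >= 1, got {blur_kernel}")

    img = image.astype(np.float64)
    truncate = ((blur_kernel - 1) / 2.0) / blur_sigma if blur_sigma > 0 else 0.0
    mag_sq = np.zeros(img.shape[:2])
    for ch in range(3):
        plane = img[..., ch]
        if blur_sigma > 0 and blur_kernel > 1:
            plane = ndimage.gaussian_filter(plane, sigma=blur_sigma, truncate=truncate)
        gx = ndimage.sobel(plane, axis=1)
        gy = ndimage.sobel(plane, axis=0)
        mag_sq += gx**2 + gy**2  # RSS over channels == sum of squared components
    mag = np.sqrt(mag_sq)
    peak = mag.max()
    if peak <= 0:
        return np.zeros_like(mag)
    return mag * (255.0 / peak)


def detect_plates(edges: np.ndarray, params: HoughParams) -> list[DetectedCircle]:
    """Circle Hough transform on a normalized edge-magnitude map.

    Pixels with edge response >= ``param1`` vote for all circles passing
    through them in the radius window; a circle's score is its raw vote
    count and must reach ``param2`` to be reported.  Surviving candidates
    are suppressed so that no two reported centers lie closer than
    ``minDist`` (the stronger circle wins), and the list is returned
    vote-descending.  ``dp`` > 1 coarsens the accumulator grid by that
    factor.  An empty list (no votes above threshold) is not an error.
    """
    edges = np.asarray(edges, dtype=np.float64)
    if edges.ndim != 2:
        raise ValueError("edge map must be a single-channel 2-D raster")
    if params.maxRadius < 1:
        return []

    scale = float(params.dp)
    if scale > 1.0:
        # coarsen the accumulator grid: smooth-downscale the magnitude map
        # (binarizing first would alias the thin rim into a dashed ring)
        h, w = edges.shape
        hh, ww = max(1, int(round(h / scale))), max(1, int(round(w / scale)))
        edges = resize(edges, (hh, ww), order=1, anti_aliasing=True)
        lo = max(1, int(math.floor(params.minRadius / scale)))
        hi = max(lo, int(math.ceil(params.maxRadius / scale)))
    else:
        lo, hi = max(1, params.minRadius), params.maxRadius
    binary = edges >= params.param1
    if not binary.any():
        return []

    # radius step 2 px keeps the search O(60-100 planes) at desk image sizes
    # while staying well inside the +/-5 px acceptance band
    step = 1 if hi - lo <= 40 else 2
    radii = np.arange(lo, hi + 1, step)
    accum = hough_circle(binary, radii, normalize=True)

    candidates: list[DetectedCircle] = []
    for plane, r in zip(accum, radii):
        votes = plane * (2.0 * math.pi * r)  # undo normalization -> raw votes
        mask = votes >= params.param2
        if not mask.any():
            continue
        # local maxima only, to avoid flooding the NMS stage
        maxed = ndimage.maximum_filter(votes, size=5)
        mask &= votes >= maxed
        ys, xs = np.nonzero(mask)
        for y, x in zip(ys, xs):
            candidates.append(
                DetectedCircle(
                    cx=float(x * scale) if scale > 1 else float(x),
                    cy=float(y * scale) if scale > 1 else float(y),
                    r=float(r * scale) if scale > 1 else float(r),
                    score=float(votes[y, x]),
                )
            )

    # vote-descending with deterministic tie-breaks: larger radius first,
    # then smaller (cy, cx)
    candidates.sort(key=lambda c: (-c.score, -c.r, c.cy, c.cx))
    kept: list[DetectedCircle] = []
    for cand in candidates:
        if all(
            math.hypot(cand.cx - k.cx, cand.cy - k.cy) >= params.minDist for k in kept
        ):
            kept.append(cand)
    return kept


def select_best_circle(
    circles: list[DetectedCircle], image_dims: tuple[int, int]
) -> DetectedCircle | None:
    """Pick the plate hypothesis that best fits: highest-vote circle fully
    inside the frame; ties broken by larger radius, then smaller (cy, cx).

    Returns None for an empty candidate list or when no circle fits.
    """
    h, w = image_dims
    inside = [
        c
        for c in circles
        if c.cx - c.r >= 0 and c.cy - c.r >= 0 and c.cx + c.r <= w - 1 and c.cy + c.r <= h - 1
    ]
    if not inside:
        return None
    return min(inside, key=lambda c: (-c.score, -c.r, c.cy, c.cx))


def crop_circle(
    image: np.ndarray, circle: DetectedCircle, target: tuple[int, int]
) -> np.ndarray:
    """Crop the circle's bounding square (clamped to the frame) and resize.

    Resizing is bilinear; output is uint8 with shape exactly ``target``.
    """
    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError("target dims must be positive")
    image = np.asarray(image)
    h, w = image.shape[:2]
    x0 = int(math.floor(circle.cx - circle.r))
    x1 = int(math.ceil(circle.cx + circle.r)) + 1
    y0 = int(math.floor(circle.cy - circle.r))
    y1 = int(math.ceil(circle.cy + circle.r)) + 1
    if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
        raise ValueError("circle lies entirely outside the image")
    x0, y0 = max(0, x0), max(0, y0)
    x1, y1 = min(w, x1), min(h, y1)
    patch = image[y0:y1, x0:x1]
    out = resize(patch.astype(np.float64), (th, tw), order=1, anti_aliasing=False)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def annotate_detections(
    image: np.ndarray, circles: list[DetectedCircle]
) -> np.ndarray:
    """Return a copy with green circle outlines and red center dots."""
    out = np.asarray(image).copy()
    h, w = out.shape[:2]
    for c in circles:
        for rr_off in (-1, 0):  # 2-px stroke
            r = int(round(c.r)) + rr_off
            if r < 1:
                continue
            ys, xs = circle_perimeter(
                int(round(c.cy)), int(round(c.cx)), r, shape=(h, w)
            )
            out[ys, xs] = (0, 255, 0)
    for c in circles:
        ys, xs = disk((int(round(c.cy)), int(round(c.cx))), 3, shape=(h, w))
        out[ys, xs] = (255, 0, 0)
    return out
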