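"""Canny edge-detection chain for joint-MRI rasters.

The chain is the classical one: Gaussian smoothing, Sobel gradients,
non-maximum suppression along the quantised gradient direction, and
double-threshold hysteresis linking.  Conventions used throughout:

* 0-based ``(row, col)`` indexing; ``x`` = column, ``y`` = row, ``y``
  increasing downward.
* Replicate padding at borders for both smoothing and gradients.
* ``gy`` is the Sobel response of the row above minus the row below, i.e.
  positive where intensity decreases downward.
* Non-maximum suppression keeps a pixel only if its magnitude is *strictly*
  greater than both neighbours along the gradient direction, so plateaus of
  constant magnitude vanish entirely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .raster import ImageRaster

__all__ = [
    "CannyParams",
    "GradientField",
    "EdgeMap",
    "gaussian_kernel",
    "smooth",
    "sobel_gradients",
    "nonmax_suppress",
    "auto_thresholds",
    "hysteresis_link",
    "canny",
    "approximation_degree",
    "extract_synovial_contour",
]

log = logging.getLogger(__name__)

# provenance codes for EdgeMap
PROV_NONE = 0
PROV_WEAK_SUPPRESSED = 1
PROV_STRONG = 2
PROV_WEAK_LINKED = 3

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_Y = np.array([[1.0, 2.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -2.0, -1.0]])


@dataclass(frozen=True)
class CannyParams:
    """Tunable parameters of the edge chain.

    ``delta`` is the Gaussian standard deviation in pixels.  ``t_high`` and
    ``t_low`` are absolute magnitude thresholds; when left unset they are
    derived per image from the ``q_high`` quantile of nonzero suppressed
    magnitudes and the ``low_ratio`` multiplier.
    """

    delta: float = 1.4
    kernel_radius: Optional[int] = None  # default ceil(3 * delta)
    t_high: Optional[float] = None
    t_low: Optional[float] = None
    q_high: float = 0.90
    low_ratio: float = 0.4
    connectivity: int = 8
    literal_direction: bool = False  # arctan(gx/gy) axis-swapped variant

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if (self.t_low is None) != (self.t_high is None):
            raise ValueError("set both t_low and t_high, or neither")
        if self.t_high is not None and not 0 <= self.t_low <= self.t_high:
            raise ValueError(
                f"need 0 <= t_low <= t_high, got ({self.t_low}, {self.t_high})"
            )
        if not 0 < self.q_high < 1:
            raise ValueError(f"q_high must be in (0, 1), got {self.q_high}")
        if not 0 < self.low_ratio <= 1:
            raise ValueError(f"low_ratio must be in (0, 1], got {self.low_ratio}")

    @property
    def radius(self) -> int:
        return self.kernel_radius if self.kernel_radius is not None else max(
            1, math.ceil(3 * self.delta)
        )


@dataclass(frozen=True)
class GradientField:
    """Per-pixel Sobel gradients of one raster.

    ``magnitude == hypot(gx, gy)`` everywhere; ``direction`` is the
    four-quadrant angle of ``(gx, gy)`` in radians, 0 by convention where
    both components vanish.
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.gx, self.gy, self.magnitude, self.direction)}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent field shapes: {shapes}")


@dataclass(frozen=True)
class EdgeMap:
    """Binary edge indicator plus a per-pixel provenance label.

    ``provenance`` holds 0 none / 1 weak-suppressed / 2 strong /
    3 weak-linked; ``edges`` is true exactly where provenance is strong or
    weak-linked.
    """

    edges: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        if self.edges.shape != self.provenance.shape:
            raise ValueError("edges and provenance shapes differ")


def _as_array(image) -> np.ndarray:
    if isinstance(image, ImageRaster):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def gaussian_kernel(delta: float, radius: int) -> np.ndarray:
    """Normalised ``(2r+1) x (2r+1)`` isotropic Gaussian kernel.

    Entries are proportional to ``exp(-(x**2 + y**2) / (2 * delta**2))`` and
    sum to exactly 1.
    """
    if not delta > 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    coords = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(coords, coords)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * delta**2))
    return k / k.sum()


def smooth(image, delta: float, radius: Optional[int] = None) -> np.ndarray:
    """Gaussian smoothing by discrete 2-D convolution, replicate borders.

    Constant images are fixed points because the kernel sums to 1.
    """
    arr = _as_array(image)
    r = radius if radius is not None else max(1, math.ceil(3 * delta))
    kernel = gaussian_kernel(delta, r)
    # symmetric kernel: correlate == convolve
    return ndimage.correlate(arr, kernel, mode="nearest")


def sobel_gradients(image, literal_direction: bool = False) -> GradientField:
    """Sobel first-difference gradients with replicate padding.

    ``gx`` weighs the column right of each pixel (1, 2, 1) against the
    column to its left; ``gy`` the row above against the row below.
    ``direction`` is ``atan2(gy, gx)`` unless ``literal_direction`` asks for
    the axis-swapped ``arctan(gx / gy)`` variant, kept for auditing only —
    non-maximum suppression always uses the conventional angle.
    """
    arr = _as_array(image)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3, got {arr.shape}")
    gx = ndimage.correlate(arr, _SOBEL_X, mode="nearest")
    gy = ndimage.correlate(arr, _SOBEL_Y, mode="nearest")
    magnitude = np.hypot(gx, gy)
    if literal_direction:
        with np.errstate(divide="ignore", invalid="ignore"):
            direction = np.arctan(np.divide(gx, gy))
        direction = np.where(np.isfinite(direction), direction, np.pi / 2)
    else:
        direction = np.arctan2(gy, gx)
    direction = np.where(magnitude == 0, 0.0, direction)
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, direction=direction)


def _sector(direction: np.ndarray) -> np.ndarray:
    """Quantise gradient angles to sectors 0/1/2/3 = 0, 45, 90, 135 deg."""
    deg = np.degrees(direction) % 180.0
    sector = np.zeros(deg.shape, dtype=np.int8)
    sector[(deg >= 22.5) & (deg < 67.5)] = 1
    sector[(deg >= 67.5) & (deg < 112.5)] = 2
    sector[(deg >= 112.5) & (deg < 157.5)] = 3
    return sector


# neighbour offsets (drow, dcol) along the gradient direction, per sector.
# gy responds to intensity increasing upward (row above minus row below), so
# the angle lives in a y-up frame: sector 1 (45 deg) points up-right on
# screen, i.e. toward (row-1, col+1).
_SECTOR_OFFSETS = {
    0: ((0, 1), (0, -1)),
    1: ((-1, 1), (1, -1)),
    2: ((1, 0), (-1, 0)),
    3: ((1, 1), (-1, -1)),
}


def nonmax_suppress(field: GradientField) -> np.ndarray:
    """Thin the gradient magnitude along the quantised gradient direction.

    Each pixel survives (keeping its original magnitude) only if strictly
    greater than both neighbours along its direction sector; out-of-bounds
    neighbours count as 0.
    """
    mag = field.magnitude
    sector = _sector(field.direction)
    h, w = mag.shape
    out = np.zeros_like(mag)
    padded = np.zeros((h + 2, w + 2))
    padded[1:-1, 1:-1] = mag
    for s, ((dr1, dc1), (dr2, dc2)) in _SECTOR_OFFSETS.items():
        sel = sector == s
        n1 = padded[1 + dr1 : 1 + dr1 + h, 1 + dc1 : 1 + dc1 + w]
        n2 = padded[1 + dr2 : 1 + dr2 + h, 1 + dc2 : 1 + dc2 + w]
        keep = sel & (mag > n1) & (mag > n2)
        out[keep] = mag[keep]
    return out


def auto_thresholds(
    suppressed: np.ndarray, q_high: float = 0.90, low_ratio: float = 0.4
) -> tuple[float, float]:
    """Derive ``(t_low, t_high)`` from the suppressed magnitude histogram.

    ``t_high`` is the nearest-rank ``q_high`` quantile of the *nonzero*
    suppressed magnitudes; ``t_low = low_ratio * t_high``.  An all-zero
    raster yields ``(0, 0)`` with a warning.
    """
    if not 0 < q_high < 1:
        raise ValueError(f"q_high must be in (0, 1), got {q_high}")
    if not 0 < low_ratio <= 1:
        raise ValueError(f"low_ratio must be in (0, 1], got {low_ratio}")
    values = np.sort(np.asarray(suppressed, dtype=np.float64).ravel())
    values = values[values > 0]
    if values.size == 0:
        log.warning("auto_thresholds: no nonzero suppressed magnitudes; (0, 0)")
        return (0.0, 0.0)
    rank = max(1, math.ceil(q_high * values.size))  # nearest-rank quantile
    t_high = float(values[rank - 1])
    return (low_ratio * t_high, t_high)


def hysteresis_link(
    suppressed: np.ndarray, t_low: float, t_high: float, connectivity: int = 8
) -> EdgeMap:
    """Double-threshold edge linking.

    Nonzero pixels ``>= t_high`` are strong; nonzero pixels in
    ``[t_low, t_high)`` are weak.  A weak pixel becomes an edge iff it is
    connected — transitively, through weak pixels, under the chosen
    connectivity — to some strong pixel.  Zero-magnitude pixels are never
    candidates.
    """
    if t_low > t_high:
        raise ValueError(f"t_low ({t_low}) > t_high ({t_high})")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    s = np.asarray(suppressed, dtype=np.float64)
    strong = (s >= t_high) & (s > 0)
    weak = (s >= t_low) & (s < t_high) & (s > 0)
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(strong | weak, structure=structure)
    linked = np.zeros(s.shape, dtype=bool)
    if n:
        has_strong = np.zeros(n + 1, dtype=bool)
        np.logical_or.at(has_strong, labels[strong], True)
        linked = has_strong[labels] & (labels > 0)
    provenance = np.full(s.shape, PROV_NONE, dtype=np.int8)
    provenance[weak & ~linked] = PROV_WEAK_SUPPRESSED
    provenance[weak & linked] = PROV_WEAK_LINKED
    provenance[strong] = PROV_STRONG
    edges = (provenance == PROV_STRONG) | (provenance == PROV_WEAK_LINKED)
    return EdgeMap(edges=edges, provenance=provenance)


@dataclass(frozen=True)
class CannyStages:
    """Intermediates of one full-chain run, for inspection."""

    smoothed: np.ndarray
    gradients: GradientField
    suppressed: np.ndarray
    thresholds: tuple[float, float]
    edge_map: EdgeMap


def canny(image, params: CannyParams = CannyParams(), return_stages: bool = False):
    """Full chain: smooth -> gradients -> NMS -> thresholds -> hysteresis."""
    smoothed = smooth(image, params.delta, params.radius)
    field = sobel_gradients(smoothed)
    suppressed = nonmax_suppress(field)
    if params.t_high is not None:
        t_low, t_high = params.t_low, params.t_high
    else:
        t_low, t_high = auto_thresholds(suppressed, params.q_high, params.low_ratio)
    edge_map = hysteresis_link(suppressed, t_low, t_high, params.connectivity)
    if return_stages:
        return CannyStages(smoothed, field, suppressed, (t_low, t_high), edge_map)
    return edge_map


def approximation_degree(f, g) -> float:
    """Discrete L2 distance between two equal-size rasters.

    ``sqrt(sum((f - g)**2))`` over all pixels — the closeness of the
    processed image to the original under the L2 norm.
    """
    fa, ga = _as_array(f), _as_array(g)
    if fa.shape != ga.shape:
        raise ValueError(f"shape mismatch: {fa.shape} vs {ga.shape}")
    return float(np.sqrt(np.sum((fa - ga) ** 2)))


def extract_synovial_contour(edge_map: EdgeMap) -> tuple[np.ndarray, bool]:
    """Pick the largest connected edge component as the synovial contour.

    Returns ``(mask, closed)`` where ``closed`` is true iff the component
    encloses a nonempty interior (flood fill from the raster border cannot
    reach every non-component pixel).  Ties between equal-size components go
    to the one whose minimal ``(row, col)`` pixel is lexicographically
    smallest.  An empty edge map yields an empty mask and ``closed=False``.
    """
    edges = edge_map.edges
    structure = ndimage.generate_binary_structure(2, 2)
    labels, n = ndimage.label(edges, structure=structure)
    if n == 0:
        return np.zeros(edges.shape, dtype=bool), False
    sizes = ndimage.sum_labels(edges, labels, index=np.arange(1, n + 1))
    best = int(np.max(sizes))
    candidates = [i + 1 for i, sz in enumerate(sizes) if int(sz) == best]
    if len(candidates) == 1:
        label = candidates[0]
    else:
        # first pixel of each candidate in raster (row-major) scan order
        def first_pixel(lbl: int) -> tuple[int, int]:
            rows, cols = np.nonzero(labels == lbl)
            order = np.lexsort((cols, rows))
            return int(rows[order[0]]), int(cols[order[0]])

        label = min(candidates, key=first_pixel)
    mask = labels == label
    filled = ndimage.binary_fill_holes(mask)
    closed = bool(filled.sum() > mask.sum())
    return mask, closed
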