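"""Reconstruction-quality metrics: MSE, PSNR and sliding-window SSIM.

SSIM here follows the plain uniform-window definition: an ``H x H`` window
slides with stride 1 over every position fully inside both rasters; per
window the luminance, contrast and structure terms

    l = (2 mu_M mu_N + C1) / (mu_M^2 + mu_N^2 + C1)
    c = (2 sigma_M sigma_N + C2) / (sigma_M^2 + sigma_N^2 + C2)
    s = (sigma_MN + C3) / (sigma_M sigma_N + C3)

are multiplied, and the overall value is the arithmetic mean over windows.
Window statistics use sample (n-1) normalisation.  No Gaussian window
weighting is applied — a deliberate departure from the most common SSIM
implementations in favour of the plain boxed window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .raster import ImageRaster

__all__ = [
    "SSIMParams",
    "SSIMResult",
    "IdenticalImagesError",
    "mse",
    "psnr",
    "window_stats",
    "ssim_components",
    "ssim",
]


class IdenticalImagesError(ValueError):
    """PSNR is infinite: the two rasters are identical (MSE = 0)."""


@dataclass(frozen=True)
class SSIMParams:
    """SSIM configuration.

    ``window`` is the side H of the H x H sliding window; ``L`` the dynamic
    range of the pixel values (255 for 8-bit).  The stabilising constants
    are ``C1 = (k1 L)**2``, ``C2 = (k2 L)**2`` and ``C3 = C2 / 2``.
    ``literal_covariance`` replaces the cross-product covariance with the
    variance of the first window (an audit mode; see docs/methods.md).
    """

    window: int = 8
    k1: float = 0.01
    k2: float = 0.03
    L: float = 255.0
    literal_covariance: bool = False

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError(f"window must be >= 2, got {self.window}")
        if not self.L > 0:
            raise ValueError(f"L must be > 0, got {self.L}")

    @property
    def C1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.k2 * self.L) ** 2

    @property
    def C3(self) -> float:
        return self.C2 / 2.0


@dataclass(frozen=True)
class SSIMResult:
    """Mean SSIM plus the per-window map and (l, c, s) components.

    ``map`` has one entry per window position (top-left anchored);
    ``value`` is its arithmetic mean.
    """

    value: float
    map: np.ndarray
    components: tuple[np.ndarray, np.ndarray, np.ndarray]


def _as_array(image) -> np.ndarray:
    if isinstance(image, ImageRaster):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def mse(I, J) -> float:
    """Mean squared error between two equal-size rasters."""
    a, b = _as_array(I), _as_array(J)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(I, J, bit_depth: int = 8) -> float:
    """Peak signal-to-noise ratio in dB: ``10 log10(MAX^2 / MSE)``.

    ``MAX = 2**bit_depth - 1``.  Identical inputs have no finite PSNR and
    raise :class:`IdenticalImagesError` rather than returning a number.
    """
    err = mse(I, J)
    if err == 0.0:
        raise IdenticalImagesError("MSE is 0: PSNR is infinite")
    peak = float((1 << bit_depth) - 1)
    return float(10.0 * np.log10(peak**2 / err))


def window_stats(M, N):
    """Sample statistics of two equal-size windows.

    Returns ``(mu_M, mu_N, var_M, var_N, cov_MN)`` with means divided by
    ``H*W`` and variances/covariance by ``H*W - 1``.
    """
    a, b = _as_array(M), _as_array(N)
    if a.shape != b.shape:
        raise ValueError(f"window shape mismatch: {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError("windows need at least 2 pixels")
    mu_m, mu_n = float(a.mean()), float(b.mean())
    dm, dn = a - mu_m, b - mu_n
    var_m = float((dm**2).sum() / (n - 1))
    var_n = float((dn**2).sum() / (n - 1))
    cov = float((dm * dn).sum() / (n - 1))
    return mu_m, mu_n, var_m, var_n, cov


def ssim_components(M, N, params: SSIMParams = SSIMParams()):
    """Luminance, contrast and structure terms for one window pair."""
    mu_m, mu_n, var_m, var_n, cov = window_stats(M, N)
    if params.literal_covariance:
        cov = var_m
    s_m, s_n = np.sqrt(var_m), np.sqrt(var_n)
    l = (2 * mu_m * mu_n + params.C1) / (mu_m**2 + mu_n**2 + params.C1)
    c = (2 * s_m * s_n + params.C2) / (var_m + var_n + params.C2)
    s = (cov + params.C3) / (s_m * s_n + params.C3)
    return float(l), float(c), float(s)


def ssim(M, N, params: SSIMParams = SSIMParams()) -> SSIMResult:
    """Mean structural similarity over all stride-1 interior windows."""
    a, b = _as_array(M), _as_array(N)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    H = params.window
    if a.shape[0] < H or a.shape[1] < H:
        raise ValueError(f"raster {a.shape} smaller than {H}x{H} window")
    wa = sliding_window_view(a, (H, H)).reshape(-1, H * H)
    wb = sliding_window_view(b, (H, H)).reshape(-1, H * H)
    n = H * H
    mu_a = wa.mean(axis=1)
    mu_b = wb.mean(axis=1)
    da = wa - mu_a[:, None]
    db = wb - mu_b[:, None]
    var_a = (da**2).sum(axis=1) / (n - 1)
    var_b = (db**2).sum(axis=1) / (n - 1)
    cov = (da * db).sum(axis=1) / (n - 1)
    if params.literal_covariance:
        cov = var_a
    s_a, s_b = np.sqrt(var_a), np.sqrt(var_b)
    l = (2 * mu_a * mu_b + params.C1) / (mu_a**2 + mu_b**2 + params.C1)
    c = (2 * s_a * s_b + params.C2) / (var_a + var_b + params.C2)
    s = (cov + params.C3) / (s_a * s_b + params.C3)
    per_window = l * c * s
    shape = (a.shape[0] - H + 1, a.shape[1] - H + 1)
    return SSIMResult(
        value=float(per_window.mean()),
        map=per_window.reshape(shape),
        components=(l.reshape(shape), c.reshape(shape), s.reshape(shape)),
    )
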