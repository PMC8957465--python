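"""Straight-line reference implementations used as test oracles.

Everything here is written independently of the package internals: plain
Python loops over lists, index clamping for replicate borders, BFS flood
fill for hysteresis.  Deliberately slow and obvious.
"""

from __future__ import annotations

import math


def _clamp(v: int, lo: int, hi: int) -> int:
    return max(lo, min(hi, v))


def naive_gaussian_kernel(delta: float, radius: int) -> list[list[float]]:
    size = 2 * radius + 1
    k = [[math.exp(-(dx * dx + dy * dy) / (2 * delta * delta))
          for dx in range(-radius, radius + 1)]
         for dy in range(-radius, radius + 1)]
    total = sum(sum(row) for row in k)
    return [[v / total for v in row] for row in k]


def naive_smooth(img: list[list[float]], delta: float, radius: int) -> list[list[float]]:
    h, w = len(img), len(img[0])
    kernel = naive_gaussian_kernel(delta, radius)
    out = [[0.0] * w for _ in range(h)]
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    v = img[_clamp(r + dr, 0, h - 1)][_clamp(c + dc, 0, w - 1)]
                    acc += v * kernel[dr + radius][dc + radius]
            out[r][c] = acc
    return out


def naive_sobel(img: list[list[float]]):
    """Per-pixel (gx, gy, magnitude) with replicate borders.

    gx: right column weighted (1, 2, 1) minus left column; gy: row above
    minus row below.
    """
    h, w = len(img), len(img[0])

    def at(r, c):
        return img[_clamp(r, 0, h - 1)][_clamp(c, 0, w - 1)]

    gx = [[0.0] * w for _ in range(h)]
    gy = [[0.0] * w for _ in range(h)]
    mag = [[0.0] * w for _ in range(h)]
    for r in range(h):
        for c in range(w):
            gx[r][c] = (
                at(r - 1, c + 1) + 2 * at(r, c + 1) + at(r + 1, c + 1)
                - at(r - 1, c - 1) - 2 * at(r, c - 1) - at(r + 1, c - 1)
            )
            gy[r][c] = (
                at(r - 1, c - 1) + 2 * at(r - 1, c) + at(r - 1, c + 1)
                - at(r + 1, c - 1) - 2 * at(r + 1, c) - at(r + 1, c + 1)
            )
            mag[r][c] = math.sqrt(gx[r][c] ** 2 + gy[r][c] ** 2)
    return gx, gy, mag


def naive_nms(gx, gy, mag):
    """Keep pixels strictly greater than both neighbours along the gradient
    direction snapped to the nearest multiple of 45 degrees (y up)."""
    h, w = len(mag), len(mag[0])
    out = [[0.0] * w for _ in range(h)]
    for r in range(h):
        for c in range(w):
            if mag[r][c] == 0:
                continue
            theta = math.degrees(math.atan2(gy[r][c], gx[r][c])) % 180.0
            # snap to nearest multiple of 45 deg, half-up at band boundaries
            snapped = math.radians(45.0 * math.floor(theta / 45.0 + 0.5))
            dc = round(math.cos(snapped))
            dr = -round(math.sin(snapped))

            def neigh(sr, sc):
                rr, cc = r + sr, c + sc
                if 0 <= rr < h and 0 <= cc < w:
                    return mag[rr][cc]
                return 0.0

            if mag[r][c] > neigh(dr, dc) and mag[r][c] > neigh(-dr, -dc):
                out[r][c] = mag[r][c]
    return out


def naive_thresholds(sup, q_high: float, low_ratio: float):
    values = sorted(v for row in sup for v in row if v > 0)
    if not values:
        return 0.0, 0.0
    rank = max(1, math.ceil(q_high * len(values)))
    t_high = values[rank - 1]
    return low_ratio * t_high, t_high


def naive_hysteresis(sup, t_low: float, t_high: float, connectivity: int = 8):
    """BFS flood fill from every strong pixel through weak pixels."""
    h, w = len(sup), len(sup[0])
    strong = [(r, c) for r in range(h) for c in range(w)
              if sup[r][c] >= t_high and sup[r][c] > 0]
    candidate = [[sup[r][c] >= t_low and sup[r][c] > 0 for c in range(w)]
                 for r in range(h)]
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    edges = [[False] * w for _ in range(h)]
    stack = list(strong)
    for r, c in strong:
        edges[r][c] = True
    while stack:
        r, c = stack.pop()
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and candidate[rr][cc] and not edges[rr][cc]:
                edges[rr][cc] = True
                stack.append((rr, cc))
    return edges


def naive_canny(img, delta: float, radius: int, q_high: float,
                low_ratio: float, connectivity: int = 8):
    smoothed = naive_smooth(img, delta, radius)
    gx, gy, mag = naive_sobel(smoothed)
    sup = naive_nms(gx, gy, mag)
    t_low, t_high = naive_thresholds(sup, q_high, low_ratio)
    return naive_hysteresis(sup, t_low, t_high, connectivity)


def naive_ssim(M, N, window: int, k1: float = 0.01, k2: float = 0.03,
               L: float = 255.0) -> float:
    """Brute-force mean SSIM over stride-1 interior windows."""
    h, w = len(M), len(M[0])
    C1, C2 = (k1 * L) ** 2, (k2 * L) ** 2
    C3 = C2 / 2
    values = []
    for r in range(h - window + 1):
        for c in range(w - window + 1):
            ma = [M[r + i][c + j] for i in range(window) for j in range(window)]
            nb = [N[r + i][c + j] for i in range(window) for j in range(window)]
            n = len(ma)
            mu_m = sum(ma) / n
            mu_n = sum(nb) / n
            var_m = sum((v - mu_m) ** 2 for v in ma) / (n - 1)
            var_n = sum((v - mu_n) ** 2 for v in nb) / (n - 1)
            cov = sum((a - mu_m) * (b - mu_n) for a, b in zip(ma, nb)) / (n - 1)
            l = (2 * mu_m * mu_n + C1) / (mu_m**2 + mu_n**2 + C1)
            cc = (2 * math.sqrt(var_m) * math.sqrt(var_n) + C2) / (var_m + var_n + C2)
            s = (cov + C3) / (math.sqrt(var_m) * math.sqrt(var_n) + C3)
            values.append(l * cc * s)
    return sum(values) / len(values)
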