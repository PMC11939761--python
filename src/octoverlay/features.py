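"""Shi-Tomasi ("good features to track") corner detection.

A pixel is trackable when the local structure tensor

    G = [[sum Ix^2,   sum Ix*Iy],
         [sum Ix*Iy,  sum Iy^2 ]]

accumulated over a square window has a large minimum eigenvalue: intensity
varies in two independent directions, so window-based tracking is
well-posed there.  On fundus imagery these pixels concentrate along the
vascular tree, whose dark edges and bifurcations are the strongest
two-dimensional structure in the scene.

Detection thresholds the minimum-eigenvalue score at a fraction of its
global maximum and applies greedy minimum-distance non-maximum suppression
in descending score order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["CornerParams", "shi_tomasi_score_map", "detect_corners", "gradients"]

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]) / 8.0


@dataclass(frozen=True)
class CornerParams:
    """Detector configuration.

    ``quality_level`` is the acceptance threshold as a fraction of the
    largest score in the frame; ``min_distance`` enforces spatial spread of
    the returned corners; ``block_size`` is the (odd) structure-tensor
    window side in pixels.  Defaults are sized for roughly-megapixel
    surgical video frames and give a dense vascular point set.
    """

    max_corners: int = 400
    quality_level: float = 0.01
    min_distance: float = 8.0
    block_size: int = 5
    gradient_kernel: str = "sobel3"

    def __post_init__(self):
        if not (0.0 < self.quality_level <= 1.0):
            raise ValueError("quality_level must be in (0, 1]")
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError("block_size must be odd and >= 3")
        if self.gradient_kernel not in ("sobel3", "central_diff"):
            raise ValueError("gradient_kernel must be 'sobel3' or 'central_diff'")


def gradients(image: np.ndarray, kernel: str = "sobel3") -> tuple[np.ndarray, np.ndarray]:
    """Image gradients (Ix, Iy) normalized to intensity units per pixel.

    ``sobel3`` uses the 3x3 Sobel operator scaled by 1/8 so that a unit
    ramp yields unit gradient; ``central_diff`` uses (I[i+1] - I[i-1]) / 2.
    Borders are handled by edge replication.
    """
    img = np.asarray(image, dtype=np.float64)
    if kernel == "sobel3":
        ix = ndimage.correlate(img, _SOBEL_X, mode="nearest")
        iy = ndimage.correlate(img, _SOBEL_X.T, mode="nearest")
    elif kernel == "central_diff":
        ix = np.empty_like(img)
        ix[:, 1:-1] = (img[:, 2:] - img[:, :-2]) * 0.5
        ix[:, 0] = img[:, 1] - img[:, 0]
        ix[:, -1] = img[:, -1] - img[:, -2]
        iy = np.empty_like(img)
        iy[1:-1, :] = (img[2:, :] - img[:-2, :]) * 0.5
        iy[0, :] = img[1, :] - img[0, :]
        iy[-1, :] = img[-1, :] - img[-2, :]
    else:
        raise ValueError(f"unknown gradient kernel {kernel!r}")
    return ix, iy


def shi_tomasi_score_map(image: np.ndarray, params: CornerParams | None = None) -> np.ndarray:
    """Per-pixel minimum eigenvalue of the windowed structure tensor.

    The tensor entries are plain (uniformly weighted) sums of Ix^2, Ix*Iy
    and Iy^2 over the ``block_size`` x ``block_size`` window, and the score
    is the closed-form smaller eigenvalue

        lambda_min = (a + c)/2 - sqrt(((a - c)/2)^2 + b^2).

    Pixels whose window extends past the image border score 0.
    """
    if params is None:
        params = CornerParams()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    bs = params.block_size
    if img.shape[0] < bs or img.shape[1] < bs:
        raise ValueError(
            f"image {img.shape} smaller than structure-tensor window {bs}x{bs}"
        )
    ix, iy = gradients(img, params.gradient_kernel)
    area = float(bs * bs)
    # uniform_filter computes window means; multiply back to plain sums
    a = ndimage.uniform_filter(ix * ix, size=bs, mode="constant") * area
    b = ndimage.uniform_filter(ix * iy, size=bs, mode="constant") * area
    c = ndimage.uniform_filter(iy * iy, size=bs, mode="constant") * area
    score = 0.5 * (a + c) - np.sqrt((0.5 * (a - c)) ** 2 + b * b)
    score = np.maximum(score, 0.0)
    r = bs // 2
    score[:r, :] = 0.0
    score[-r:, :] = 0.0
    score[:, :r] = 0.0
    score[:, -r:] = 0.0
    return score


def detect_corners(image: np.ndarray, params: CornerParams | None = None) -> np.ndarray:
    """Detect Shi-Tomasi corners; returns an (n, 2) float array of (x, y).

    Candidates with score >= quality_level * max(score) are visited in
    descending score order (ties broken by ascending (y, x)); a candidate
    is accepted unless it lies within ``min_distance`` (Euclidean, strict)
    of an already-accepted corner, until ``max_corners`` are collected.
    Positions are the integer coordinates of score-map pixels.
    """
    if params is None:
        params = CornerParams()
    score = shi_tomasi_score_map(image, params)
    smax = float(score.max())
    if smax <= 0.0:
        return np.empty((0, 2), dtype=np.float64)
    ys, xs = np.nonzero(score >= params.quality_level * smax)
    vals = score[ys, xs]
    order = np.lexsort((xs, ys, -vals))
    xs, ys = xs[order], ys[order]

    min_d = params.min_distance
    min_d2 = min_d * min_d
    cell = max(min_d, 1.0)
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    out: list[tuple[float, float]] = []
    for x, y in zip(xs, ys):
        cx, cy = int(x // cell), int(y // cell)
        ok = True
        for gx in (cx - 1, cx, cx + 1):
            for gy in (cy - 1, cy, cy + 1):
                for (ax, ay) in grid.get((gx, gy), ()):
                    if (ax - x) ** 2 + (ay - y) ** 2 < min_d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            out.append((float(x), float(y)))
            grid.setdefault((cx, cy), []).append((float(x), float(y)))
            if len(out) >= params.max_corners:
                break
    return np.asarray(out, dtype=np.float64).reshape(-1, 2)
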