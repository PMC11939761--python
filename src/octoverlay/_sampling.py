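"""Bilinear sampling and inverse-mapping warps shared across modules.

Sampling is clamp-to-edge: query coordinates are clipped to the image
rectangle before interpolation, so windows that straddle the border reuse
edge values.  Coordinates follow the package convention (x = column,
y = row, pixel centers at integers).
"""

from __future__ import annotations

import numpy as np

from .geometry import Homography, apply_homography, invert


def bilinear_sample(img: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sample a 2D image at float coordinates with bilinear interpolation.

    ``x`` and ``y`` may have any (common) shape; the result has that shape.
    Out-of-range coordinates are clamped to the edge.
    """
    h, w = img.shape[:2]
    x = np.clip(x, 0.0, w - 1.0)
    y = np.clip(y, 0.0, h - 1.0)
    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    if w > 1:
        x0 = np.minimum(x0, w - 2)
    if h > 1:
        y0 = np.minimum(y0, h - 2)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = x - x0
    fy = y - y0
    ia = img[y0, x0]
    ib = img[y0, x1]
    ic = img[y1, x0]
    id_ = img[y1, x1]
    top = ia * (1.0 - fx) + ib * fx
    bot = ic * (1.0 - fx) + id_ * fx
    return top * (1.0 - fy) + bot * fy


def inverse_warp(
    img: np.ndarray, h: Homography, out_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Warp ``img`` by homography ``h`` (img coords -> output coords).

    Every output pixel ``p`` is filled with ``img`` sampled bilinearly at
    ``h^{-1}(p)``.  Returns ``(warped, support)`` where ``support`` marks
    output pixels whose source coordinate lies inside the image rectangle;
    outside the support the warped value is 0.

    ``img`` may be 2D (grayscale/scalar) or (H, W, C).
    """
    oh, ow = out_shape
    hinv = invert(h)
    xs, ys = np.meshgrid(np.arange(ow, dtype=np.float64), np.arange(oh, dtype=np.float64))
    src = apply_homography(hinv, np.stack([xs.ravel(), ys.ravel()], axis=1))
    sx = src[:, 0].reshape(oh, ow)
    sy = src[:, 1].reshape(oh, ow)
    ih, iw = img.shape[:2]
    support = (sx >= 0.0) & (sx <= iw - 1.0) & (sy >= 0.0) & (sy <= ih - 1.0)
    if img.ndim == 2:
        warped = bilinear_sample(img, sx, sy)
        warped[~support] = 0.0
    else:
        warped = np.stack(
            [bilinear_sample(img[..., c], sx, sy) for c in range(img.shape[2])], axis=-1
        )
        warped[~support] = 0.0
    return warped, support


def nearest_warp_mask(mask: np.ndarray, h: Homography, out_shape: tuple[int, int]) -> np.ndarray:
    """Warp a binary mask by ``h`` with nearest-neighbor sampling."""
    oh, ow = out_shape
    hinv = invert(h)
    xs, ys = np.meshgrid(np.arange(ow, dtype=np.float64), np.arange(oh, dtype=np.float64))
    src = apply_homography(hinv, np.stack([xs.ravel(), ys.ravel()], axis=1))
    sx = np.rint(src[:, 0]).astype(np.int64).reshape(oh, ow)
    sy = np.rint(src[:, 1]).astype(np.int64).reshape(oh, ow)
    ih, iw = mask.shape
    inside = (sx >= 0) & (sx < iw) & (sy >= 0) & (sy < ih)
    out = np.zeros(out_shape, dtype=bool)
    out[inside] = mask[sy[inside], sx[inside]]
    return out
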