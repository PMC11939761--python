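"""Iterative pyramidal Lucas-Kanade sparse optical flow.

Tracks a set of feature points from one grayscale frame into the next by
minimizing the windowed sum of squared intensity differences, coarse to
fine over an image pyramid.  At each pyramid level the displacement is
refined by Newton steps ``d <- d + G^{-1} b`` where ``G`` is the spatial
gradient (structure) tensor of the first frame over the window and ``b``
the gradient-weighted temporal difference; sub-pixel samples come from
bilinear interpolation with clamp-to-edge behavior at the border.

A forward-backward check re-tracks each point from the second frame back
to the first and discards points whose round trip does not return close to
the start; this is the verification behind the per-transition "successful
matching" statistic reported by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from ._sampling import bilinear_sample

__all__ = ["FlowParams", "TrackStatus", "TrackResult", "build_pyramid", "track_points_lk"]

_BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


class TrackStatus(IntEnum):
    """Per-point outcome of Lucas-Kanade tracking."""

    OK = 0
    LOST_BOUNDS = 1
    ILL_CONDITIONED = 2
    DIVERGED = 3
    FB_FAILED = 4


@dataclass(frozen=True)
class FlowParams:
    """Tracker configuration.

    ``window_radius`` r gives a (2r+1)^2 integration window;
    ``min_eigen_threshold`` rejects points whose gradient tensor, scaled by
    window area, is too close to singular for a stable solve (textureless
    regions); ``fb_threshold`` (pixels) bounds the forward-backward round
    trip, with 0 disabling the check.
    """

    window_radius: int = 10
    pyramid_levels: int = 3
    max_iterations: int = 30
    epsilon: float = 0.01
    min_eigen_threshold: float = 1e-4
    fb_threshold: float = 1.0

    def __post_init__(self):
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class TrackResult:
    """Result of tracking n points: next-frame positions, status, residual.

    ``residual`` is the mean absolute intensity difference over the window
    at the converged displacement (finest level); it is NaN for points
    whose status is not OK/FB_FAILED.  ``fb_error`` holds the round-trip
    displacement where the forward-backward check ran, else NaN.
    """

    points: np.ndarray
    status: np.ndarray
    residual: np.ndarray
    fb_error: np.ndarray

    @property
    def ok(self) -> np.ndarray:
        return self.status == TrackStatus.OK


def build_pyramid(image: np.ndarray, levels: int) -> list[np.ndarray]:
    """Gaussian-like pyramid: 5-tap binomial blur then 2x decimation.

    Level 0 is the input itself (as float64); each coarser level is the
    previous one convolved separably with [1, 4, 6, 4, 1]/16 (edge
    replication at the border) and decimated to even rows and columns.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if min(img.shape) < 2 ** (levels - 1):
        raise ValueError(
            f"image {img.shape} too small for {levels} pyramid levels"
        )
    pyr = [img]
    for _ in range(levels - 1):
        prev = pyr[-1]
        padded = np.pad(prev, 2, mode="edge")
        tmp = _conv1d_valid(padded, _BINOMIAL5, axis=1)
        tmp = _conv1d_valid(tmp, _BINOMIAL5, axis=0)
        pyr.append(tmp[::2, ::2])
    return pyr


def _conv1d_valid(img: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    """Correlate along one axis, 'valid' output (kernel assumed symmetric)."""
    k = len(kernel)
    if axis == 1:
        out = np.zeros((img.shape[0], img.shape[1] - k + 1))
        for i in range(k):
            out += kernel[i] * img[:, i : img.shape[1] - k + 1 + i]
    else:
        out = np.zeros((img.shape[0] - k + 1, img.shape[1]))
        for i in range(k):
            out += kernel[i] * img[i : img.shape[0] - k + 1 + i, :]
    return out


def _central_gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gx = np.empty_like(img)
    gx[:, 1:-1] = (img[:, 2:] - img[:, :-2]) * 0.5
    gx[:, 0] = img[:, 1] - img[:, 0]
    gx[:, -1] = img[:, -1] - img[:, -2]
    gy = np.empty_like(img)
    gy[1:-1, :] = (img[2:, :] - img[:-2, :]) * 0.5
    gy[0, :] = img[1, :] - img[0, :]
    gy[-1, :] = img[-1, :] - img[-2, :]
    return gx, gy


def _track_once(
    pyr0: list[np.ndarray],
    pyr1: list[np.ndarray],
    pts: np.ndarray,
    params: FlowParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Track pts (n, 2) from pyr0's frame to pyr1's frame.

    Returns (new_points, status, residual); vectorized over points.
    """
    n = len(pts)
    r = params.window_radius
    k_area = float((2 * r + 1) ** 2)
    ax = np.arange(-r, r + 1, dtype=np.float64)
    ox, oy = np.meshgrid(ax, ax)
    ox = ox.ravel()[None, :]  # (1, k)
    oy = oy.ravel()[None, :]

    d = np.zeros((n, 2), dtype=np.float64)
    status = np.full(n, int(TrackStatus.OK), dtype=np.int64)
    residual = np.full(n, np.nan)
    levels = len(pyr0)

    for lvl in range(levels - 1, -1, -1):
        img0, img1 = pyr0[lvl], pyr1[lvl]
        h, w = img0.shape
        gx_img, gy_img = _central_gradients(img0)
        p = pts / (2.0 ** lvl)
        x0 = p[:, 0:1] + ox  # (n, k)
        y0 = p[:, 1:2] + oy
        win0 = bilinear_sample(img0, x0, y0)
        gxs = bilinear_sample(gx_img, x0, y0)
        gys = bilinear_sample(gy_img, x0, y0)
        gxx = np.sum(gxs * gxs, axis=1)
        gxy = np.sum(gxs * gys, axis=1)
        gyy = np.sum(gys * gys, axis=1)
        det = gxx * gyy - gxy * gxy
        lam_min = 0.5 * ((gxx + gyy) - np.hypot(gxx - gyy, 2.0 * gxy))
        if lvl == 0:
            ill = (status == TrackStatus.OK) & (lam_min / k_area < params.min_eigen_threshold)
            status[ill] = TrackStatus.ILL_CONDITIONED
        solvable = det > 1e-12 * np.maximum(gxx + gyy, 1e-30) ** 2
        solvable &= det > 0

        conv = np.zeros(n, dtype=bool)
        last_step = np.zeros(n)
        for _ in range(params.max_iterations):
            act = np.flatnonzero((status == TrackStatus.OK) & solvable & ~conv)
            if act.size == 0:
                break
            x1 = x0[act] + d[act, 0:1]
            y1 = y0[act] + d[act, 1:2]
            win1 = bilinear_sample(img1, x1, y1)
            diff = win0[act] - win1
            bx = np.sum(gxs[act] * diff, axis=1)
            by = np.sum(gys[act] * diff, axis=1)
            inv_det = 1.0 / det[act]
            dx = (gyy[act] * bx - gxy[act] * by) * inv_det
            dy = (gxx[act] * by - gxy[act] * bx) * inv_det
            d[act, 0] += dx
            d[act, 1] += dy
            step = np.hypot(dx, dy)
            last_step[act] = step
            conv[act] = step < params.epsilon

        cur = p + d
        if lvl == 0:
            diverged = (status == TrackStatus.OK) & solvable & ~conv & (last_step > 0.5)
            status[diverged] = TrackStatus.DIVERGED
            out = (
                (cur[:, 0] < 0.0)
                | (cur[:, 0] > w - 1.0)
                | (cur[:, 1] < 0.0)
                | (cur[:, 1] > h - 1.0)
            )
            status[(status == TrackStatus.OK) & out] = TrackStatus.LOST_BOUNDS
            ok = status == TrackStatus.OK
            if np.any(ok):
                x1 = x0[ok] + d[ok, 0:1]
                y1 = y0[ok] + d[ok, 1:2]
                win1 = bilinear_sample(img1, x1, y1)
                residual[ok] = np.mean(np.abs(win0[ok] - win1), axis=1)
        else:
            # far outside the level image: give up on the point early
            margin = 2.0 * r
            out = (
                (cur[:, 0] < -margin)
                | (cur[:, 0] > w - 1.0 + margin)
                | (cur[:, 1] < -margin)
                | (cur[:, 1] > h - 1.0 + margin)
            )
            status[(status == TrackStatus.OK) & out] = TrackStatus.LOST_BOUNDS
            d *= 2.0

    return pts + d, status, residual


def track_points_lk(
    prev: np.ndarray,
    next: np.ndarray,
    points: np.ndarray,
    params: FlowParams | None = None,
) -> TrackResult:
    """Track ``points`` from ``prev`` into ``next``.

    Images must be 2D and share a shape; ``points`` is an (n, 2) array of
    (x, y) positions inside ``prev``.  Tracking failure is reported per
    point through :class:`TrackStatus`, never as an exception.
    """
    if params is None:
        params = FlowParams()
    prev = np.asarray(prev, dtype=np.float64)
    next = np.asarray(next, dtype=np.float64)
    if prev.ndim != 2 or next.ndim != 2:
        raise ValueError("expected 2D grayscale frames")
    if prev.shape != next.shape:
        raise ValueError(f"frame shape mismatch: {prev.shape} vs {next.shape}")
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64)).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        z = np.empty(0)
        return TrackResult(pts.copy(), np.empty(0, dtype=np.int64), z.copy(), z.copy())

    levels = params.pyramid_levels
    pyr0 = build_pyramid(prev, levels)
    pyr1 = build_pyramid(next, levels)
    new_pts, status, residual = _track_once(pyr0, pyr1, pts, params)

    fb_error = np.full(n, np.nan)
    if params.fb_threshold > 0:
        ok = status == TrackStatus.OK
        if np.any(ok):
            back_pts, back_status, _ = _track_once(pyr1, pyr0, new_pts[ok], params)
            rt = np.linalg.norm(back_pts - pts[ok], axis=1)
            fb_error[ok] = rt
            failed = (back_status != TrackStatus.OK) | (rt > params.fb_threshold)
            idx = np.flatnonzero(ok)[failed]
            status[idx] = TrackStatus.FB_FAILED

    # no silent NaNs: any non-finite coordinate must carry a failure status
    bad = ~np.all(np.isfinite(new_pts), axis=1)
    status[bad & (status == TrackStatus.OK)] = TrackStatus.DIVERGED
    return TrackResult(new_pts, status, residual, fb_error)
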