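"""Planar homography algebra and estimation from point correspondences.

The map-to-video and frame-to-frame alignments in this package are modelled
as 3x3 projective transforms (homographies) acting on homogeneous pixel
coordinates ``[x, y, 1]^T``.  The coordinate convention throughout the
package is 0-based with pixel centers at integer coordinates, ``x`` running
rightward along columns and ``y`` downward along rows.

Estimation is the Hartley-normalized Direct Linear Transformation (DLT):
both point sets are similarity-normalized (centroid to the origin, mean
distance to sqrt(2)), the stacked 2n x 9 linear system is solved by SVD,
and the result is denormalized.  Robust estimation from noisy tracked
correspondences uses RANSAC over 4-point DLT samples with a reprojection
inlier test and a final DLT refit on the consensus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "DegenerateGeometryError",
    "PointAtInfinityError",
    "TransformFailure",
    "Point2D",
    "PointPair",
    "Homography",
    "RansacParams",
    "apply_homography",
    "compose",
    "invert",
    "estimate_homography_dlt",
    "estimate_transform_ransac",
    "reprojection_errors",
]

_DET_EPS = 1e-12
_H33_EPS = 1e-8


class GeometryError(ValueError):
    """Base class for geometric estimation failures."""


class DegenerateGeometryError(GeometryError):
    """Point configuration does not determine a homography (e.g. collinear)."""


class PointAtInfinityError(GeometryError):
    """A point maps to the line at infinity (projective denominator ~ 0)."""


class TransformFailure(GeometryError):
    """Robust estimation could not find a sufficient consensus set."""


class Point2D(NamedTuple):
    """A 2D pixel-coordinate point (x = column, y = row)."""

    x: float
    y: float


class PointPair(NamedTuple):
    """A correspondence: ``src`` in the source frame, ``dst`` in the target."""

    src: Point2D
    dst: Point2D


@dataclass(frozen=True)
class Homography:
    """An invertible 3x3 projective transform.

    The stored matrix is normalized so that ``m[2, 2] == 1`` whenever that
    entry is meaningfully nonzero, and to unit Frobenius norm otherwise.
    Construct through :meth:`from_matrix`, which validates invertibility.
    """

    m: np.ndarray

    @staticmethod
    def from_matrix(m: np.ndarray) -> "Homography":
        m = np.asarray(m, dtype=np.float64)
        if m.shape != (3, 3):
            raise GeometryError(f"homography matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise GeometryError("homography matrix contains non-finite entries")
        fro = float(np.linalg.norm(m))
        if fro == 0.0:
            raise GeometryError("homography matrix is zero")
        if abs(np.linalg.det(m / fro)) <= _DET_EPS:
            raise GeometryError("homography matrix is singular")
        # normalize by h33 directly so renormalizing an already-normalized
        # matrix is a bitwise no-op (division by exactly 1.0)
        if abs(m[2, 2]) / fro > _H33_EPS:
            mn = m / m[2, 2]
        else:
            mn = m / fro
        mn = mn.copy()
        mn.flags.writeable = False
        return Homography(mn)

    @staticmethod
    def identity() -> "Homography":
        return Homography.from_matrix(np.eye(3))

    @staticmethod
    def translation(tx: float, ty: float) -> "Homography":
        m = np.eye(3)
        m[0, 2] = tx
        m[1, 2] = ty
        return Homography.from_matrix(m)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.m, dtype=dtype)


@dataclass(frozen=True)
class RansacParams:
    """RANSAC configuration for robust frame-to-frame estimation.

    ``inlier_threshold`` is the reprojection distance in pixels below which
    a correspondence counts toward the consensus; ``min_inliers`` is the
    smallest consensus set accepted as a valid transform.
    """

    inlier_threshold: float = 3.0
    max_iterations: int = 2000
    min_inliers: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.inlier_threshold <= 0:
            raise ValueError("inlier_threshold must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.min_inliers < 4:
            raise ValueError("min_inliers must be >= 4")


def as_point_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a correspondence collection to ``(src, dst)`` float arrays.

    Accepts a sequence of :class:`PointPair`, an ``(n, 4)`` array of
    ``src_x, src_y, dst_x, dst_y`` rows, or an ``(n, 2, 2)`` array.
    """
    if isinstance(pairs, tuple) and len(pairs) == 2:
        src, dst = (np.asarray(a, dtype=np.float64) for a in pairs)
    else:
        arr = np.asarray(
            [(p.src.x, p.src.y, p.dst.x, p.dst.y) for p in pairs]
            if len(pairs) and isinstance(pairs[0], PointPair)
            else pairs,
            dtype=np.float64,
        )
        if arr.ndim == 3 and arr.shape[1:] == (2, 2):
            src, dst = arr[:, 0, :], arr[:, 1, :]
        elif arr.ndim == 2 and arr.shape[1] == 4:
            src, dst = arr[:, :2], arr[:, 2:]
        else:
            raise GeometryError(f"cannot interpret correspondences of shape {arr.shape}")
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise GeometryError("src/dst must both be (n, 2) point arrays")
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
        raise GeometryError("correspondences contain non-finite coordinates")
    return src, dst


def apply_homography(h: Homography, p) -> np.ndarray:
    """Apply ``h`` to a point or an ``(n, 2)`` array of points.

    Returns ``(u/w, v/w)`` where ``[u, v, w]^T = m @ [x, y, 1]^T``.
    Raises :class:`PointAtInfinityError` if any projective denominator
    ``|w|`` falls below 1e-12.
    """
    pts = np.asarray(p, dtype=np.float64)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    m = h.m
    w = m[2, 0] * pts[:, 0] + m[2, 1] * pts[:, 1] + m[2, 2]
    if np.any(np.abs(w) < 1e-12):
        raise PointAtInfinityError("point maps to infinity (denominator ~ 0)")
    u = m[0, 0] * pts[:, 0] + m[0, 1] * pts[:, 1] + m[0, 2]
    v = m[1, 0] * pts[:, 0] + m[1, 1] * pts[:, 1] + m[1, 2]
    out = np.stack([u / w, v / w], axis=1)
    return out[0] if single else out


def compose(h2: Homography, h1: Homography) -> Homography:
    """Composition applying ``h1`` first, then ``h2`` (matrix product m2 @ m1)."""
    return Homography.from_matrix(h2.m @ h1.m)


def invert(h: Homography) -> Homography:
    """Inverse transform; raises :class:`GeometryError` on a singular matrix."""
    try:
        return Homography.from_matrix(np.linalg.inv(h.m))
    except np.linalg.LinAlgError as e:  # pragma: no cover - guarded by invariant
        raise GeometryError("cannot invert singular homography") from e


def reprojection_errors(h: Homography, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Euclidean distances ``|h(src_i) - dst_i|`` in pixels."""
    proj = apply_homography(h, src)
    return np.linalg.norm(proj - np.asarray(dst, dtype=np.float64), axis=1)


def _hartley_normalize(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity transform sending the centroid to the origin and the mean
    distance from it to sqrt(2); returns ``(T, T_applied_points)``.

    Raises :class:`DegenerateGeometryError` when the points are (numerically)
    collinear or coincident, in which case no homography is determined.
    """
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    sv = np.linalg.svd(centered, compute_uv=False)
    scale_ref = max(float(sv[0]), 1.0)
    if sv[1] <= 1e-9 * scale_ref:
        raise DegenerateGeometryError(
            "degenerate point configuration: points are collinear or coincident"
        )
    mean_dist = np.mean(np.linalg.norm(centered, axis=1))
    s = np.sqrt(2.0) / mean_dist
    t = np.array(
        [
            [s, 0.0, -s * centroid[0]],
            [0.0, s, -s * centroid[1]],
            [0.0, 0.0, 1.0],
        ]
    )
    return t, centered * s


def estimate_homography_dlt(pairs, dst=None) -> Homography:
    """Estimate a homography from >= 4 correspondences by normalized DLT.

    Parameters
    ----------
    pairs
        Either a correspondence collection (sequence of :class:`PointPair`
        or an ``(n, 4)`` array), or the ``(n, 2)`` source points when
        ``dst`` is given separately.
    dst
        Optional ``(n, 2)`` destination points.

    The fit is exact (to numerical precision) when the correspondences are
    noiseless and consistent with a single homography.
    """
    if dst is not None:
        src, dst = as_point_arrays((pairs, dst))
    else:
        src, dst = as_point_arrays(pairs)
    n = len(src)
    if n < 4:
        raise GeometryError(f"need >= 4 point pairs for DLT, got {n}")
    ts, srcn = _hartley_normalize(src)
    td, dstn = _hartley_normalize(dst)

    a = np.zeros((2 * n, 9))
    x, y = srcn[:, 0], srcn[:, 1]
    u, v = dstn[:, 0], dstn[:, 1]
    a[0::2, 0] = -x
    a[0::2, 1] = -y
    a[0::2, 2] = -1.0
    a[0::2, 6] = u * x
    a[0::2, 7] = u * y
    a[0::2, 8] = u
    a[1::2, 3] = -x
    a[1::2, 4] = -y
    a[1::2, 5] = -1.0
    a[1::2, 6] = v * x
    a[1::2, 7] = v * y
    a[1::2, 8] = v
    _, _, vt = np.linalg.svd(a)
    hn = vt[-1].reshape(3, 3)
    m = np.linalg.inv(td) @ hn @ ts
    try:
        return Homography.from_matrix(m)
    except GeometryError as e:
        raise DegenerateGeometryError(
            "DLT produced a singular transform; point configuration is degenerate"
        ) from e


def estimate_transform_ransac(
    pairs, params: RansacParams | None = None, dst=None
) -> tuple[Homography, np.ndarray]:
    """Robustly estimate a homography from noisy correspondences.

    Standard RANSAC: repeatedly sample 4 pairs, fit by DLT, and count the
    correspondences whose reprojection error is below
    ``params.inlier_threshold``.  The best consensus set is refit by DLT and
    the inlier mask is recomputed under the refit transform, so every
    reported inlier satisfies the threshold exactly.  Deterministic given
    ``params.seed``.

    Returns ``(homography, inlier_mask)``; raises :class:`TransformFailure`
    when no consensus of at least ``params.min_inliers`` exists.
    """
    if params is None:
        params = RansacParams()
    if dst is not None:
        src, dst = as_point_arrays((pairs, dst))
    else:
        src, dst = as_point_arrays(pairs)
    n = len(src)
    if n < 4:
        raise GeometryError(f"need >= 4 point pairs for RANSAC, got {n}")

    rng = np.random.default_rng(params.seed)
    best_count = 0
    best_err_sum = np.inf
    best_mask: np.ndarray | None = None
    for _ in range(params.max_iterations):
        idx = rng.choice(n, size=4, replace=False)
        try:
            h = estimate_homography_dlt(src[idx], dst[idx])
            err = reprojection_errors(h, src, dst)
        except GeometryError:
            continue
        mask = err < params.inlier_threshold
        count = int(mask.sum())
        err_sum = float(err[mask].sum())
        if count > best_count or (count == best_count and err_sum < best_err_sum):
            best_count, best_err_sum, best_mask = count, err_sum, mask
        if count == n:
            break

    if best_mask is None or best_count < params.min_inliers:
        raise TransformFailure(
            f"RANSAC consensus of {best_count} below min_inliers={params.min_inliers}"
        )
    h = estimate_homography_dlt(src[best_mask], dst[best_mask])
    final_err = reprojection_errors(h, src, dst)
    final_mask = final_err < params.inlier_threshold
    if int(final_mask.sum()) < params.min_inliers:
        raise TransformFailure(
            "consensus collapsed below min_inliers after refit"
        )
    return h, final_mask
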