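"""Evaluation quantities for overlay tracking.

``success_rate`` and ``vessel_proximity_fraction`` mirror the two
statistics used to evaluate the tracker on surgical video: the fraction
of frame transitions with a successful flow/matching update, and the
fraction of feature points lying near the vascular tree.  The drift
measures compare an estimated cumulative transform chain against ground
truth and are therefore only available on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Homography, apply_homography
from .pipeline import TrackingReport

__all__ = [
    "DriftMeasure",
    "success_rate",
    "summarize_rates",
    "vessel_proximity_fraction",
    "overlay_drift",
]


@dataclass
class DriftMeasure:
    """Per-frame mean control-grid reprojection discrepancy, in pixels."""

    per_frame_error: np.ndarray
    final_error: float
    max_error: float


def success_rate(report: TrackingReport) -> float:
    """Percentage of transitions flagged successful in a tracking report."""
    if not report.records:
        raise ValueError("cannot compute a success rate from an empty report")
    flags = np.array([r.success for r in report.records], dtype=bool)
    return 100.0 * float(flags.mean())


def summarize_rates(rates: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation of per-video success rates.

    Matches the usual per-video aggregation of multi-recording studies
    (each video contributes one rate, regardless of its frame count).
    """
    r = np.asarray(rates, dtype=np.float64)
    if r.size == 0:
        raise ValueError("no rates to summarize")
    sd = float(r.std(ddof=1)) if r.size > 1 else 0.0
    return float(r.mean()), sd


def vessel_proximity_fraction(
    points: np.ndarray, vessel_mask: np.ndarray, d: float = 5.0
) -> float:
    """Fraction of points within distance ``d`` of the vessel mask.

    Distance is exact Euclidean distance from the (possibly sub-pixel)
    point to the nearest mask-true pixel center, computed with a k-d tree
    over the mask coordinates.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64)).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("empty point list")
    mask = np.asarray(vessel_mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty vessel mask")
    if d < 0:
        raise ValueError("distance d must be >= 0")
    tree = cKDTree(np.stack([xs, ys], axis=1).astype(np.float64))
    dist, _ = tree.query(pts)
    return float(np.mean(dist <= d))


def overlay_drift(
    estimated: Sequence[Homography],
    truth: Sequence[Homography],
    grid: np.ndarray,
) -> DriftMeasure:
    """Mean per-frame reprojection discrepancy between two transform chains.

    For each frame k the grid points are mapped through both the estimated
    and the ground-truth cumulative transforms and the mean Euclidean
    distance between the two images is recorded.
    """
    if len(estimated) != len(truth):
        raise ValueError(
            f"chain length mismatch: {len(estimated)} estimated vs {len(truth)} truth"
        )
    pts = np.atleast_2d(np.asarray(grid, dtype=np.float64)).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("empty control grid")
    errs = np.empty(len(estimated))
    for k, (he, ht) in enumerate(zip(estimated, truth)):
        pe = apply_homography(he, pts)
        pt = apply_homography(ht, pts)
        errs[k] = float(np.mean(np.linalg.norm(pe - pt, axis=1)))
    return DriftMeasure(
        per_frame_error=errs,
        final_error=float(errs[-1]),
        max_error=float(errs.max()),
    )
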