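"""End-to-end overlay tracking.

The pipeline keeps a preoperative OCT thickness map registered to a moving
surgical video.  Alignment is initialized once from manually selected
landmark correspondences between the map and frame 0 (homography by
normalized DLT).  For every subsequent frame transition, Shi-Tomasi
corners detected on the previous frame are tracked into the next frame
with pyramidal Lucas-Kanade flow; a robust homography fitted to the
surviving tracks is chained onto the cumulative map-to-frame transform,
so the rendered overlay follows the retina through eye and camera motion.

A transition succeeds when enough forward-backward-verified tracks remain
and the robust fit reaches a minimum inlier ratio.  On failure the
cumulative transform is held (``hold_last``): the overlay freezes rather
than jumping, and tracking resumes from the last successfully aligned
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import geometry
from ._sampling import bilinear_sample
from .colormap import apply_colormap
from .features import CornerParams, detect_corners
from .flow import FlowParams, TrackStatus, track_points_lk
from .geometry import (
    GeometryError,
    Homography,
    RansacParams,
    TransformFailure,
    compose,
    estimate_homography_dlt,
    estimate_transform_ransac,
    invert,
    reprojection_errors,
)

__all__ = [
    "PipelineParams",
    "OverlayState",
    "FrameTransitionRecord",
    "TrackingReport",
    "to_gray",
    "to_uint8",
    "initialize_alignment",
    "cumulative_chain",
    "advance_frame",
    "render_overlay",
    "run_sequence",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PipelineParams:
    """Aggregate configuration for the overlay tracker.

    A transition is declared successful when at least
    ``min_tracks_for_update`` verified tracks survive and the robust fit
    keeps an inlier fraction of at least ``success_min_inlier_ratio``.
    ``failure_policy`` chooses between freezing the overlay (``hold_last``)
    and aborting the run (``abort``).
    """

    corner: CornerParams = field(default_factory=CornerParams)
    flow: FlowParams = field(default_factory=FlowParams)
    ransac: RansacParams = field(default_factory=RansacParams)
    min_tracks_for_update: int = 25
    success_min_inlier_ratio: float = 0.5
    failure_policy: str = "hold_last"
    overlay_alpha: float = 0.4
    colormap: str = "thickness_pseudocolor"

    def __post_init__(self):
        if not (0.0 <= self.overlay_alpha <= 1.0):
            raise ValueError("overlay_alpha must be in [0, 1]")
        if self.failure_policy not in ("hold_last", "abort"):
            raise ValueError("failure_policy must be 'hold_last' or 'abort'")


@dataclass
class OverlayState:
    """Cumulative map-to-current-frame alignment plus bookkeeping."""

    h_map_to_frame: Homography
    frame_index: int = 0
    last_transition_ok: bool = True
    frames_since_success: int = 0


@dataclass
class FrameTransitionRecord:
    """Diagnostics for one frame-to-frame transition.

    ``transform`` is the estimated previous-to-next homography and is
    present exactly when ``success`` is true.
    """

    frame_index: int
    n_detected: int
    n_tracked_ok: int
    n_inliers: int
    success: bool
    mean_fb_error: float
    transform: Homography | None = None


@dataclass
class TrackingReport:
    """Per-transition records for a tracked sequence of ``n_frames`` frames."""

    records: list[FrameTransitionRecord]
    n_frames: int


class PipelineError(RuntimeError):
    """Unrecoverable pipeline failure (initialization or abort policy)."""


def cumulative_chain(report: TrackingReport, h0: Homography) -> list[Homography]:
    """Cumulative map-to-frame transforms implied by a tracking report.

    Element 0 is ``h0`` (the map-to-frame-0 alignment); each successful
    transition composes its transform onto the chain, each failed one
    holds the previous value — exactly the ``hold_last`` rendering path.
    """
    chain = [h0]
    h = h0
    for r in report.records:
        if r.success and r.transform is not None:
            h = compose(r.transform, h)
        chain.append(h)
    return chain


def to_gray(frame: np.ndarray) -> np.ndarray:
    """Convert a frame to float64 grayscale in [0, 1].

    8-bit integer input is divided by 255; RGB is collapsed with the
    Rec.601 luma weights 0.299/0.587/0.114.
    """
    img = np.asarray(frame)
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    elif img.dtype == np.uint16:
        img = img.astype(np.float64) / 65535.0
    else:
        img = img.astype(np.float64)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    return img


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Quantize a float image in [0, 1] to uint8 with round-half-even."""
    return np.clip(np.rint(np.asarray(img, dtype=np.float64) * 255.0), 0, 255).astype(
        np.uint8
    )


def initialize_alignment(
    oct_map_shape: tuple[int, int],
    frame0: np.ndarray,
    landmarks,
) -> OverlayState:
    """Estimate the map-to-frame-0 homography from landmark pairs.

    ``landmarks`` are correspondences with ``src`` in OCT-map pixel
    coordinates and ``dst`` in frame-0 pixel coordinates; at least four
    non-degenerate pairs are required (clinical practice uses five).
    """
    src, dst = geometry.as_point_arrays(landmarks)
    if len(src) < 4:
        raise GeometryError(f"initialization needs >= 4 landmark pairs, got {len(src)}")
    h = estimate_homography_dlt(src, dst)
    return OverlayState(h_map_to_frame=h, frame_index=0)


def _fit_affine(src: np.ndarray, dst: np.ndarray) -> Homography:
    """Least-squares affine fit (6 dof) as a low-track-count fallback."""
    n = len(src)
    a = np.zeros((2 * n, 6))
    a[0::2, 0] = src[:, 0]
    a[0::2, 1] = src[:, 1]
    a[0::2, 2] = 1.0
    a[1::2, 3] = src[:, 0]
    a[1::2, 4] = src[:, 1]
    a[1::2, 5] = 1.0
    rhs = dst.ravel()
    coef, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    m = np.array(
        [
            [coef[0], coef[1], coef[2]],
            [coef[3], coef[4], coef[5]],
            [0.0, 0.0, 1.0],
        ]
    )
    return Homography.from_matrix(m)


def advance_frame(
    state: OverlayState,
    prev: np.ndarray,
    next: np.ndarray,
    params: PipelineParams | None = None,
) -> tuple[OverlayState, FrameTransitionRecord]:
    """Advance the alignment by one frame transition.

    Corners are detected on ``prev``, tracked into ``next``, and the
    surviving (status OK, forward-backward verified) correspondences feed
    a RANSAC homography fit.  On success the cumulative map-to-frame
    transform is composed with the estimated transition; on failure it is
    held unchanged (``hold_last``) or the run is aborted, per
    ``failure_policy``.  Tracking failure is a recorded outcome, not an
    exception.
    """
    if params is None:
        params = PipelineParams()
    prev_g = to_gray(prev)
    next_g = to_gray(next)
    if prev_g.shape != next_g.shape:
        raise ValueError(f"frame shape mismatch: {prev_g.shape} vs {next_g.shape}")

    corners = detect_corners(prev_g, params.corner)
    n_detected = len(corners)
    n_ok = 0
    n_inliers = 0
    mean_fb = float("nan")
    transform: Homography | None = None
    success = False

    if n_detected > 0:
        tr = track_points_lk(prev_g, next_g, corners, params.flow)
        ok = tr.ok
        n_ok = int(ok.sum())
        fb = tr.fb_error[np.isfinite(tr.fb_error)]
        if fb.size:
            mean_fb = float(fb.mean())
        if n_ok >= params.min_tracks_for_update:
            src, dst = corners[ok], tr.points[ok]
            if np.array_equal(src, dst):
                # exactly zero flow (static scene): the transform is the
                # identity by construction, not a least-squares estimate
                t = Homography.identity()
                n_inliers = n_ok
            else:
                try:
                    t, mask = estimate_transform_ransac((src, dst), params.ransac)
                    n_inliers = int(mask.sum())
                except TransformFailure:
                    t = None
                    if n_ok >= 4:
                        # degenerate consensus: least-squares affine fallback
                        t = _fit_affine(src, dst)
                        err = reprojection_errors(t, src, dst)
                        mask = err < params.ransac.inlier_threshold
                        n_inliers = int(mask.sum())
                        if n_inliers < 4:
                            t = None
            if t is not None and n_inliers / n_ok >= params.success_min_inlier_ratio:
                success = True
                transform = t

    if success:
        new_h = compose(transform, state.h_map_to_frame)
        new_state = OverlayState(
            h_map_to_frame=new_h,
            frame_index=state.frame_index + 1,
            last_transition_ok=True,
            frames_since_success=0,
        )
    else:
        if params.failure_policy == "abort":
            raise PipelineError(
                f"tracking failed at transition into frame {state.frame_index + 1}"
            )
        new_state = OverlayState(
            h_map_to_frame=state.h_map_to_frame,
            frame_index=state.frame_index + 1,
            last_transition_ok=False,
            frames_since_success=state.frames_since_success + 1,
        )

    record = FrameTransitionRecord(
        frame_index=state.frame_index + 1,
        n_detected=n_detected,
        n_tracked_ok=n_ok,
        n_inliers=n_inliers,
        success=success,
        mean_fb_error=mean_fb,
        transform=transform,
    )
    return new_state, record


def render_overlay(
    frame: np.ndarray,
    oct_map: np.ndarray,
    h: Homography,
    params: PipelineParams | None = None,
) -> np.ndarray:
    """Composite the pseudocolored map onto a frame under homography ``h``.

    Inverse warping: each output pixel inside the warped map support
    samples the pseudocolored map bilinearly at ``h^{-1}(p)`` and is
    alpha-blended with the frame; pixels outside the support pass the
    frame through unchanged.  Returns float RGB in [0, 1].
    """
    if params is None:
        params = PipelineParams()
    fr = np.asarray(frame)
    if fr.dtype == np.uint8:
        fr = fr.astype(np.float64) / 255.0
    else:
        fr = fr.astype(np.float64)
    if fr.ndim == 2:
        fr = np.repeat(fr[..., None], 3, axis=-1)

    m = np.asarray(oct_map)
    if m.ndim == 3:
        # pre-rendered RGB map: used as-is
        color_map = m.astype(np.float64) / 255.0 if m.dtype == np.uint8 else m.astype(np.float64)
        color_map = color_map[..., :3]
    else:
        if m.dtype == np.uint8:
            m = m.astype(np.float64) / 255.0
        elif m.dtype == np.uint16:
            m = m.astype(np.float64) / 65535.0
        color_map = apply_colormap(m, params.colormap)

    oh, ow = fr.shape[:2]
    hinv = invert(h)
    xs, ys = np.meshgrid(np.arange(ow, dtype=np.float64), np.arange(oh, dtype=np.float64))
    src = geometry.apply_homography(hinv, np.stack([xs.ravel(), ys.ravel()], axis=1))
    sx = src[:, 0].reshape(oh, ow)
    sy = src[:, 1].reshape(oh, ow)
    mh, mw = color_map.shape[:2]
    support = (sx >= 0.0) & (sx <= mw - 1.0) & (sy >= 0.0) & (sy <= mh - 1.0)

    out = fr.copy()
    if np.any(support):
        a = params.overlay_alpha
        for c in range(3):
            sampled = bilinear_sample(color_map[..., c], sx[support], sy[support])
            out[..., c][support] = (1.0 - a) * fr[..., c][support] + a * sampled
    return out


def run_sequence(
    frames: Sequence[np.ndarray],
    oct_map: np.ndarray,
    landmarks,
    params: PipelineParams | None = None,
    render: bool = True,
) -> tuple[list[np.ndarray], TrackingReport]:
    """Track a whole frame sequence and render the overlay per frame.

    Initializes on frame 0 from the landmark pairs, then folds
    :func:`advance_frame` over consecutive transitions.  After a failed
    transition, tracking resumes from the last successfully aligned frame
    (whose cumulative transform the held overlay still refers to) so a
    single corrupt frame costs one transition, not the rest of the run.

    Returns ``(overlays, report)``: one uint8 RGB overlay per input frame
    when ``render`` is true (an empty list otherwise) and one transition
    record per consecutive frame pair.
    """
    if params is None:
        params = PipelineParams()
    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    try:
        state = initialize_alignment(np.asarray(oct_map).shape[:2], frames[0], landmarks)
    except GeometryError as e:
        raise PipelineError(f"initialization failed: {e}") from e

    overlays: list[np.ndarray] = []
    if render:
        overlays.append(to_uint8(render_overlay(frames[0], oct_map, state.h_map_to_frame, params)))
    records: list[FrameTransitionRecord] = []
    ref_frame = frames[0]  # last successfully aligned frame
    for k in range(1, len(frames)):
        state, record = advance_frame(state, ref_frame, frames[k], params)
        records.append(record)
        if record.success:
            ref_frame = frames[k]
        if render:
            overlays.append(
                to_uint8(render_overlay(frames[k], oct_map, state.h_map_to_frame, params))
            )
    return overlays, TrackingReport(records=records, n_frames=len(frames))
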