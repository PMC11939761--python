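"""Ground-truth synthetic fundus video generator.

Surgical recordings of membrane peeling are not publicly available, so
every stage of the tracker is exercised on phantoms built here: a
fundus-like scene (circular illuminated field of view, warm smooth
background texture, a dark recursively branching vascular tree), smooth
homographic camera/eye motion with exact per-frame ground truth, optional
degradations (a moving instrument-shaft occluder, blur, illumination
drift), a smooth thickness-map phantom registered to frame 0, and
landmark pairs consistent with the map-to-frame-0 transform.

Motion is realized by warping a single master frame, which keeps the
per-frame ground-truth transforms exact at the cost of a little
interpolation softening.  Every output is a pure function of the
parameter manifest, so datasets are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from ._sampling import inverse_warp, nearest_warp_mask
from .geometry import Homography, Point2D, PointPair, apply_homography

__all__ = [
    "PhantomParams",
    "MotionParams",
    "DegradeParams",
    "SyntheticDataset",
    "generate_fundus_phantom",
    "generate_motion_sequence",
    "generate_thickness_phantom",
    "generate_dataset",
    "dataset_from_manifest",
]

MANIFEST_SCHEMA = "octoverlay-synthetic/1"


@dataclass(frozen=True)
class PhantomParams:
    """Fundus phantom scene parameters.

    The default 320 x 240 canvas is a scaled-down stand-in for WSVGA
    surgical video; the vascular tree grows from a seeded disc location
    with ``n_trunks`` primary vessels branching ``branch_depth`` times,
    widths decaying by ``width_decay`` per generation.
    """

    width: int = 320
    height: int = 240
    fov_radius_frac: float = 0.45
    n_trunks: int = 5
    branch_depth: int = 4
    branch_angle_sd: float = 0.35
    vessel_width0: float = 3.5
    width_decay: float = 0.75
    background_noise_sd: float = 0.02
    texture_scale: float = 24.0
    seed: int = 0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("phantom dimensions must be positive")
        if not (0.0 < self.fov_radius_frac <= 0.5):
            raise ValueError("fov_radius_frac must be in (0, 0.5]")
        if self.vessel_width0 <= 0:
            raise ValueError("vessel_width0 must be positive")


@dataclass(frozen=True)
class MotionParams:
    """Smooth homographic motion model.

    Per-frame increments of (tx, ty, rotation, log-scale, perspective
    h31/h32) follow an AR(1) process (coefficient ``smoothing``) driven by
    Gaussian innovations, emulating smooth surgeon/eye motion rather than
    white-noise jitter.  Increments are composed about the image center.
    """

    n_frames: int = 200
    translation_sd: float = 0.4
    rotation_sd: float = 0.0015
    log_scale_sd: float = 0.0008
    perspective_sd: float = 2e-6
    smoothing: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 <= self.smoothing < 1.0):
            raise ValueError("smoothing must be in [0, 1)")
        for name in ("translation_sd", "rotation_sd", "log_scale_sd", "perspective_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DegradeParams:
    """Optional degradations applied after warping.

    The occluder is a dark instrument shaft anchored at the field edge
    whose tip moves along a seeded linear path across the sequence; it is
    rendered after warping because the instrument moves independently of
    the retina.
    """

    occluder: bool = False
    occluder_width: float = 20.0
    blur_sd: float = 0.0
    illum_drift: float = 0.0
    seed: int = 0


@dataclass
class SyntheticDataset:
    """A complete phantom sequence with exact ground truth.

    ``truth_cumulative[k]`` maps frame-0 coordinates to frame-k
    coordinates; ``thickness_map`` is registered to frame-0 coordinates
    through ``map_to_frame0`` (identity by default), and ``landmarks``
    pair map points with their frame-0 images under that transform.
    """

    frames: list[np.ndarray]
    vessel_masks: list[np.ndarray]
    truth_cumulative: list[Homography]
    thickness_map: np.ndarray
    landmarks: list[PointPair]
    manifest: dict


def _draw_segment(darkness, mask, p0, p1, width):
    """Rasterize one anti-aliased vessel segment into the accumulators."""
    h, w = darkness.shape
    half = width / 2.0
    pad = half + 2.0
    x_lo = max(int(math.floor(min(p0[0], p1[0]) - pad)), 0)
    x_hi = min(int(math.ceil(max(p0[0], p1[0]) + pad)) + 1, w)
    y_lo = max(int(math.floor(min(p0[1], p1[1]) - pad)), 0)
    y_hi = min(int(math.ceil(max(p0[1], p1[1]) + pad)) + 1, h)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    xs, ys = np.meshgrid(
        np.arange(x_lo, x_hi, dtype=np.float64), np.arange(y_lo, y_hi, dtype=np.float64)
    )
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    seg2 = dx * dx + dy * dy
    if seg2 < 1e-12:
        t = np.zeros_like(xs)
    else:
        t = np.clip(((xs - p0[0]) * dx + (ys - p0[1]) * dy) / seg2, 0.0, 1.0)
    cx = p0[0] + t * dx
    cy = p0[1] + t * dy
    dist = np.hypot(xs - cx, ys - cy)
    aa = np.clip(half + 0.5 - dist, 0.0, 1.0)
    region_d = darkness[y_lo:y_hi, x_lo:x_hi]
    np.maximum(region_d, aa, out=region_d)
    mask[y_lo:y_hi, x_lo:x_hi] |= dist <= half


def _grow_branch(rng, params, segments, pos, angle, width, depth, step_len, fov_c, fov_r):
    n_steps = int(rng.integers(2, 5))
    for _ in range(n_steps):
        angle += float(rng.normal(0.0, params.branch_angle_sd * 0.4))
        new = (pos[0] + step_len * math.cos(angle), pos[1] + step_len * math.sin(angle))
        segments.append((pos, new, width))
        pos = new
        if math.hypot(pos[0] - fov_c[0], pos[1] - fov_c[1]) > fov_r * 1.02:
            return
    if depth > 0:
        split = 0.35 + abs(float(rng.normal(0.0, params.branch_angle_sd)))
        new_w = max(width * params.width_decay, 0.6)
        _grow_branch(rng, params, segments, pos, angle - split, new_w, depth - 1, step_len * 0.85, fov_c, fov_r)
        _grow_branch(rng, params, segments, pos, angle + split, new_w, depth - 1, step_len * 0.85, fov_c, fov_r)


_FUNDUS_BASE = np.array([0.82, 0.45, 0.18])
_VESSEL_COLOR = np.array([0.32, 0.07, 0.05])


def generate_fundus_phantom(
    params: PhantomParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the master fundus frame and its exact vessel mask.

    Returns ``(frame0, vessel_mask)`` with ``frame0`` float RGB in [0, 1]
    (exactly zero outside the circular field of view) and ``vessel_mask``
    boolean, true precisely on rasterized vessel pixels.  Deterministic
    given ``params.seed``.
    """
    if params is None:
        params = PhantomParams()
    rng = np.random.default_rng(params.seed)
    w, h = params.width, params.height
    fov_c = ((w - 1) / 2.0, (h - 1) / 2.0)
    fov_r = params.fov_radius_frac * min(w, h)

    # smooth warm background texture
    tex = ndimage.gaussian_filter(
        rng.standard_normal((h, w)), params.texture_scale / 2.0, mode="reflect"
    )
    sd = tex.std()
    if sd > 0:
        tex = tex / sd

    # vascular tree grown from a seeded disc location inside the FOV
    disc_angle = float(rng.uniform(0.0, 2.0 * math.pi))
    disc = (
        fov_c[0] + 0.55 * fov_r * math.cos(disc_angle),
        fov_c[1] + 0.55 * fov_r * math.sin(disc_angle),
    )
    segments: list[tuple] = []
    step_len = fov_r / (params.branch_depth + 1.5)
    for i in range(params.n_trunks):
        base = math.atan2(fov_c[1] - disc[1], fov_c[0] - disc[0])
        spread = (i / max(params.n_trunks - 1, 1) - 0.5) * 2.4
        angle = base + spread + float(rng.normal(0.0, 0.2))
        _grow_branch(
            rng, params, segments, disc, angle, params.vessel_width0,
            params.branch_depth, step_len, fov_c, fov_r,
        )
    darkness = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=bool)
    for p0, p1, width in segments:
        _draw_segment(darkness, mask, p0, p1, width)

    frame = _FUNDUS_BASE[None, None, :] * (1.0 + 0.18 * tex)[..., None]
    frame = frame * (1.0 - darkness[..., None]) + _VESSEL_COLOR[None, None, :] * darkness[..., None]
    noise = rng.normal(0.0, params.background_noise_sd, (h, w))
    frame = frame + noise[..., None]

    xs, ys = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
    dist = np.hypot(xs - fov_c[0], ys - fov_c[1])
    vignette = np.clip((fov_r - dist) / 3.0, 0.0, 1.0)  # 3 px feathered rim
    frame = np.clip(frame, 0.0, 1.0) * vignette[..., None]
    mask &= dist <= fov_r
    return frame, mask


def generate_motion_sequence(
    params: MotionParams | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> list[Homography]:
    """Cumulative ground-truth transforms for a smooth camera-motion track.

    Element 0 is the identity; element k maps frame-0 coordinates to
    frame-k coordinates.  Each per-frame increment is a small similarity
    plus perspective jitter composed about ``center``.
    """
    if params is None:
        params = MotionParams()
    rng = np.random.default_rng(params.seed)
    sds = np.array(
        [
            params.translation_sd,
            params.translation_sd,
            params.rotation_sd,
            params.log_scale_sd,
            params.perspective_sd,
            params.perspective_sd,
        ]
    )
    cx, cy = center
    t_c = np.array([[1.0, 0.0, cx], [0.0, 1.0, cy], [0.0, 0.0, 1.0]])
    t_ci = np.array([[1.0, 0.0, -cx], [0.0, 1.0, -cy], [0.0, 0.0, 1.0]])

    out = [Homography.identity()]
    z = np.zeros(6)
    for _ in range(params.n_frames - 1):
        z = params.smoothing * z + rng.standard_normal(6) * sds
        tx, ty, th, ls, p1, p2 = z
        s = math.exp(ls)
        a = np.array(
            [
                [s * math.cos(th), -s * math.sin(th), tx],
                [s * math.sin(th), s * math.cos(th), ty],
                [p1, p2, 1.0],
            ]
        )
        inc = t_c @ a @ t_ci
        out.append(Homography.from_matrix(inc @ out[-1].m))
    return out


def generate_thickness_phantom(
    width: int, height: int, n_blobs: int = 6, seed: int = 0
) -> np.ndarray:
    """A smooth scalar thickness-map phantom in [0, 1].

    A constant base plane plus ``n_blobs`` seeded anisotropic Gaussian
    bumps, rescaled to span [0, 1] (left at the base value when there are
    no bumps).  Smooth by construction: the finite-difference gradient is
    bounded by a few times 1/sigma_min of the generating bumps.
    """
    rng = np.random.default_rng(seed)
    base = np.full((height, width), 0.35)
    xs, ys = np.meshgrid(np.arange(width, dtype=np.float64), np.arange(height, dtype=np.float64))
    for _ in range(n_blobs):
        cx = rng.uniform(0.2 * width, 0.8 * width)
        cy = rng.uniform(0.2 * height, 0.8 * height)
        sx = rng.uniform(15.0, 45.0)
        sy = rng.uniform(15.0, 45.0)
        th = rng.uniform(0.0, math.pi)
        amp = rng.uniform(0.2, 0.6)
        xr = (xs - cx) * math.cos(th) + (ys - cy) * math.sin(th)
        yr = -(xs - cx) * math.sin(th) + (ys - cy) * math.cos(th)
        base = base + amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2))
    ptp = base.max() - base.min()
    if ptp > 0:
        base = (base - base.min()) / ptp
    return np.clip(base, 0.0, 1.0)


def _landmark_points(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Five well-spread map points: FOV center plus four at 0.6 R."""
    w, h = params.width, params.height
    fov_c = ((w - 1) / 2.0, (h - 1) / 2.0)
    fov_r = params.fov_radius_frac * min(w, h)
    pts = [fov_c]
    a0 = float(rng.uniform(0.0, 2.0 * math.pi))
    for i in range(4):
        a = a0 + i * math.pi / 2.0 + float(rng.normal(0.0, 0.1))
        pts.append(
            (fov_c[0] + 0.6 * fov_r * math.cos(a), fov_c[1] + 0.6 * fov_r * math.sin(a))
        )
    return np.asarray(pts)


def generate_dataset(
    phantom: PhantomParams | None = None,
    motion: MotionParams | None = None,
    degrade: DegradeParams | None = None,
    map_to_frame0: Homography | None = None,
) -> SyntheticDataset:
    """Generate a full phantom sequence with ground truth.

    Frame k is the master frame inverse-warped through the cumulative
    ground-truth transform (bilinear, then 8-bit quantization), followed
    by the configured degradations; vessel masks are warped with
    nearest-neighbor sampling.  The manifest records every parameter, and
    :func:`dataset_from_manifest` rebuilds the dataset bit-identically.
    """
    if phantom is None:
        phantom = PhantomParams()
    if motion is None:
        motion = MotionParams()
    if degrade is None:
        degrade = DegradeParams()
    if map_to_frame0 is None:
        map_to_frame0 = Homography.identity()

    w, h = phantom.width, phantom.height
    frame0, mask0 = generate_fundus_phantom(phantom)
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    truth = generate_motion_sequence(motion, center=center)
    n = len(truth)

    thickness = generate_thickness_phantom(w, h, n_blobs=6, seed=phantom.seed + 101)

    lm_rng = np.random.default_rng(phantom.seed + 202)
    map_pts = _landmark_points(phantom, lm_rng)
    # landmark sources live in map coordinates; their frame-0 images are
    # the same points pushed through the map->frame0 transform
    dst_pts = apply_homography(map_to_frame0, map_pts)
    landmarks = [
        PointPair(Point2D(*s), Point2D(*d)) for s, d in zip(map_pts, dst_pts)
    ]

    occ_rng = np.random.default_rng(degrade.seed + 303)
    fov_r = phantom.fov_radius_frac * min(w, h)
    if degrade.occluder:
        anchor_a = float(occ_rng.uniform(0.0, 2.0 * math.pi))
        anchor = (
            center[0] + 1.05 * fov_r * math.cos(anchor_a),
            center[1] + 1.05 * fov_r * math.sin(anchor_a),
        )
        tip_start = (
            center[0] + 0.5 * fov_r * math.cos(anchor_a + 2.2),
            center[1] + 0.5 * fov_r * math.sin(anchor_a + 2.2),
        )
        tip_end = (
            center[0] + 0.5 * fov_r * math.cos(anchor_a - 2.2),
            center[1] + 0.5 * fov_r * math.sin(anchor_a - 2.2),
        )

    frames: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for k in range(n):
        if k == 0:
            fr = frame0.copy()
            mk = mask0.copy()
        else:
            fr, _ = inverse_warp(frame0, truth[k], (h, w))
            mk = nearest_warp_mask(mask0, truth[k], (h, w))
        if degrade.occluder:
            t = k / max(n - 1, 1)
            tip = (
                tip_start[0] + t * (tip_end[0] - tip_start[0]),
                tip_start[1] + t * (tip_end[1] - tip_start[1]),
            )
            shade = np.zeros((h, w))
            occ_mask = np.zeros((h, w), dtype=bool)
            _draw_segment(shade, occ_mask, anchor, tip, degrade.occluder_width)
            fr = fr * (1.0 - 0.85 * shade[..., None])
        if degrade.blur_sd > 0:
            fr = np.stack(
                [ndimage.gaussian_filter(fr[..., c], degrade.blur_sd, mode="nearest") for c in range(3)],
                axis=-1,
            )
        if degrade.illum_drift != 0.0:
            fr = fr * (1.0 + degrade.illum_drift * math.sin(2.0 * math.pi * k / n))
        frames.append(
            np.clip(np.rint(np.clip(fr, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)
        )
        masks.append(mk)

    manifest = {
        "schema": MANIFEST_SCHEMA,
        "phantom": asdict(phantom),
        "motion": asdict(motion),
        "degrade": asdict(degrade),
        "map_to_frame0": map_to_frame0.m.tolist(),
    }
    return SyntheticDataset(
        frames=frames,
        vessel_masks=masks,
        truth_cumulative=truth,
        thickness_map=thickness,
        landmarks=landmarks,
        manifest=manifest,
    )


def dataset_from_manifest(manifest: dict) -> SyntheticDataset:
    """Rebuild a dataset from its manifest (bit-identical regeneration)."""
    if manifest.get("schema") != MANIFEST_SCHEMA:
        raise ValueError(f"unsupported manifest schema {manifest.get('schema')!r}")
    return generate_dataset(
        phantom=PhantomParams(**manifest["phantom"]),
        motion=MotionParams(**manifest["motion"]),
        degrade=DegradeParams(**manifest["degrade"]),
        map_to_frame0=Homography.from_matrix(np.asarray(manifest["map_to_frame0"])),
    )
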