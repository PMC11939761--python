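"""Phantom generation: determinism, geometry, and ground-truth consistency."""

import math

import numpy as np
import pytest

import octoverlay as ov
from octoverlay.geometry import apply_homography
from octoverlay.synthetic import (
    DegradeParams,
    MotionParams,
    PhantomParams,
    dataset_from_manifest,
    generate_dataset,
    generate_fundus_phantom,
    generate_motion_sequence,
    generate_thickness_phantom,
)


class TestFundusPhantom:
    def test_deterministic_given_seed(self):
        f1, m1 = generate_fundus_phantom(PhantomParams(seed=7))
        f2, m2 = generate_fundus_phantom(PhantomParams(seed=7))
        assert np.array_equal(f1, f2)
        assert np.array_equal(m1, m2)

    def test_outside_fov_is_black(self, phantom_frame):
        frame, _ = phantom_frame
        h, w = frame.shape[:2]
        fov_c = ((w - 1) / 2.0, (h - 1) / 2.0)
        fov_r = 0.45 * min(w, h)
        xs, ys = np.meshgrid(np.arange(w), np.arange(h))
        outside = np.hypot(xs - fov_c[0], ys - fov_c[1]) > fov_r
        assert np.all(frame[outside] == 0.0)

    def test_vessel_coverage_fraction(self, phantom_frame):
        # regression bound on the default seed-0 tree density
        _, mask = phantom_frame
        h, w = mask.shape
        fov_area = math.pi * (0.45 * min(w, h)) ** 2
        frac = mask.sum() / fov_area
        assert 0.02 <= frac <= 0.15

    def test_mask_lies_on_dark_pixels(self, phantom_frame):
        frame, mask = phantom_frame
        gray = frame @ np.array([0.299, 0.587, 0.114])
        assert gray[mask].mean() < gray[~mask & (gray > 0)].mean()


class TestMotion:
    def test_zero_sds_give_identities(self):
        seq = generate_motion_sequence(
            MotionParams(n_frames=10, translation_sd=0, rotation_sd=0,
                         log_scale_sd=0, perspective_sd=0)
        )
        for h in seq:
            np.testing.assert_array_equal(h.m, np.eye(3))

    def test_single_frame_is_identity(self):
        seq = generate_motion_sequence(MotionParams(n_frames=1))
        assert len(seq) == 1
        np.testing.assert_array_equal(seq[0].m, np.eye(3))

    def test_per_transition_corner_displacement_bound(self):
        # frozen seed-0 check of motion amplitude at the frame corners
        params = MotionParams(n_frames=200, seed=0)
        seq = generate_motion_sequence(params, center=(159.5, 119.5))
        corners = np.array([[0.0, 0.0], [319.0, 0.0], [0.0, 239.0], [319.0, 239.0]])
        diag = math.hypot(320, 240)
        bound = 4.0 * (params.translation_sd + diag * params.rotation_sd)
        worst = 0.0
        for k in range(1, len(seq)):
            prev = apply_homography(seq[k - 1], corners)
            cur = apply_homography(seq[k], corners)
            worst = max(worst, float(np.linalg.norm(cur - prev, axis=1).max()))
        assert worst <= bound


class TestThicknessPhantom:
    def test_no_blobs_is_constant(self):
        m = generate_thickness_phantom(64, 48, n_blobs=0, seed=1)
        assert np.ptp(m) == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_values_in_unit_interval(self, seed):
        m = generate_thickness_phantom(80, 60, n_blobs=5, seed=seed)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_gradient_bound(self):
        # bumps have sigma >= 15 px, so after unit rescaling the finite
        # difference gradient stays below 4 / sigma_min
        m = generate_thickness_phantom(160, 120, n_blobs=6, seed=2)
        gy, gx = np.gradient(m)
        assert np.hypot(gx, gy).max() <= 4.0 / 15.0


class TestDataset:
    def test_static_sequence_is_constant(self):
        ds = generate_dataset(
            PhantomParams(seed=1, width=128, height=96),
            MotionParams(n_frames=5, translation_sd=0, rotation_sd=0,
                         log_scale_sd=0, perspective_sd=0),
        )
        for fr in ds.frames[1:]:
            assert np.array_equal(fr, ds.frames[0])

    def test_lengths_and_identity_start(self, clean_dataset):
        ds = clean_dataset
        assert len(ds.frames) == len(ds.truth_cumulative) == len(ds.vessel_masks)
        np.testing.assert_array_equal(ds.truth_cumulative[0].m, np.eye(3))

    def test_frames_match_direct_warp_oracle(self, clean_dataset):
        # frame k sampled at vessel-interior control points equals frame 0
        # pulled through the ground-truth transform, within quantization
        ds = clean_dataset
        k = 50
        frame0 = np.asarray(ds.frames[0], dtype=np.float64) / 255.0
        framek = np.asarray(ds.frames[k], dtype=np.float64) / 255.0
        h, w = frame0.shape[:2]
        ys, xs = np.nonzero(ds.vessel_masks[k])
        keep = (xs > 20) & (xs < w - 20) & (ys > 20) & (ys < h - 20)
        pts_k = np.stack([xs[keep], ys[keep]], axis=1)[::50].astype(np.float64)
        src = apply_homography(ov.invert(ds.truth_cumulative[k]), pts_k)
        from octoverlay._sampling import bilinear_sample

        for c in range(3):
            ref = bilinear_sample(frame0[..., c], src[:, 0], src[:, 1])
            got = framek[pts_k[:, 1].astype(int), pts_k[:, 0].astype(int), c]
            assert np.abs(ref - got).max() <= 2.0 / 255.0

    def test_landmarks_consistent_with_map_transform(self, clean_dataset):
        src = np.array([[p.src.x, p.src.y] for p in clean_dataset.landmarks])
        dst = np.array([[p.dst.x, p.dst.y] for p in clean_dataset.landmarks])
        assert len(src) == 5
        # identity map->frame0 transform by default
        assert np.abs(src - dst).max() < 1e-9

    def test_manifest_roundtrip_is_bit_identical(self):
        ds = generate_dataset(
            PhantomParams(seed=4, width=96, height=80),
            MotionParams(n_frames=4, seed=4),
            DegradeParams(occluder=True, blur_sd=0.5, seed=4),
        )
        ds2 = dataset_from_manifest(ds.manifest)
        assert all(np.array_equal(a, b) for a, b in zip(ds.frames, ds2.frames))
        assert all(
            np.array_equal(a.m, b.m)
            for a, b in zip(ds.truth_cumulative, ds2.truth_cumulative)
        )
        assert np.array_equal(ds.thickness_map, ds2.thickness_map)

    def test_occluder_covers_at_most_15pct_of_fov(self):
        params = PhantomParams(seed=0)
        ds = generate_dataset(
            params,
            MotionParams(n_frames=10, translation_sd=0, rotation_sd=0,
                         log_scale_sd=0, perspective_sd=0),
            DegradeParams(occluder=True, seed=0),
        )
        fov_area = math.pi * (params.fov_radius_frac * min(params.width, params.height)) ** 2
        clean = generate_dataset(
            params,
            MotionParams(n_frames=10, translation_sd=0, rotation_sd=0,
                         log_scale_sd=0, perspective_sd=0),
        )
        for k in (0, 5, 9):
            occluded = (
                np.abs(
                    np.asarray(ds.frames[k], int) - np.asarray(clean.frames[k], int)
                ).max(axis=2)
                > 30
            )
            assert occluded.sum() <= 0.15 * fov_area
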