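"""Shared fixtures: phantoms, textures, and the reference clean run.

The expensive 200-frame clean-sequence run is session-scoped so the
end-to-end drift, success-rate and determinism checks share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import octoverlay as ov
from octoverlay.metrics import overlay_drift
from octoverlay.pipeline import cumulative_chain, initialize_alignment


def multiscale_texture(seed: int, shape: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Band-limited texture with structure at several scales.

    Mimics the multi-scale content of fundus frames (fine texture plus
    coarse vessels) so coarse pyramid levels stay informative; periodic
    (wrap-mode filtering) so Fourier shifting is exact.
    """
    rng = np.random.default_rng(seed)
    t = np.zeros(shape)
    for sigma, w in [(2.0, 1.0), (4.0, 1.5), (8.0, 2.0)]:
        t += w * ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (t - t.min()) / np.ptp(t)


def interior_grid(shape: tuple[int, int], margin: int = 40, step: int = 8) -> np.ndarray:
    h, w = shape
    xs, ys = np.meshgrid(
        np.arange(margin, w - margin, step, dtype=np.float64),
        np.arange(margin, h - margin, step, dtype=np.float64),
    )
    return np.stack([xs.ravel(), ys.ravel()], axis=1)


@pytest.fixture(scope="session")
def phantom_frame():
    """Default seed-0 fundus phantom: (float RGB frame, vessel mask)."""
    return ov.generate_fundus_phantom(ov.PhantomParams(seed=0))


@pytest.fixture(scope="session")
def clean_dataset():
    """The reference clean sequence: seed-0 phantom, 200 frames, default motion."""
    return ov.generate_dataset(
        ov.PhantomParams(seed=0), ov.MotionParams(n_frames=200, seed=0)
    )


@pytest.fixture(scope="session")
def clean_run(clean_dataset):
    """Tracking report + drift of the default pipeline on the clean sequence."""
    ds = clean_dataset
    _, report = ov.run_sequence(
        ds.frames, ds.thickness_map, ds.landmarks, render=False
    )
    state = initialize_alignment(ds.thickness_map.shape, ds.frames[0], ds.landmarks)
    est = cumulative_chain(report, state.h_map_to_frame)
    truth = [ov.compose(t, state.h_map_to_frame) for t in ds.truth_cumulative]
    grid = interior_grid((240, 320), margin=60, step=40)
    drift = overlay_drift(est, truth, grid)
    return report, drift
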