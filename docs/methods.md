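# Methods

## Problem and model

During epiretinal membrane peeling the surgeon works from a live video
view of the retina while the most informative structural data — the
preoperative OCT retinal thickness map — sits on a different screen in a
different coordinate frame. `octoverlay` keeps that map registered to the
moving video so it can be rendered as a translucent pseudocolor overlay.

The retina seen through an operating microscope is treated as a plane, so
two views of it are related by a 3×3 projective transform (homography)
acting on homogeneous pixel coordinates. Two transforms are maintained:

* **H₀ : map → frame 0** — estimated once from ≥4 (typically 5) manually
  selected landmark correspondences;
* **Tₖ : frame k−1 → frame k** — estimated per transition from tracked
  feature points.

The cumulative map-to-frame-k alignment is the chain Hₖ = Tₖ · Hₖ₋₁, with
H₀ from the landmarks. All coordinates are 0-based, x along columns, y
along rows, pixel centers at integers.

### Homography estimation

Estimation is the normalized Direct Linear Transformation: both point
sets are similarity-normalized (centroid at the origin, mean distance
√2), the 2n×9 stacked constraint system is solved by SVD (right singular
vector of the smallest singular value), and the result is denormalized.
Normalization is essential for conditioning when coordinates are in the
hundreds of pixels. The returned matrix is scaled so h₃₃ = 1 when that
entry is meaningfully nonzero (unit Frobenius norm otherwise); the
scaling divides by h₃₃ directly so renormalizing an already-normalized
matrix changes no bits — this keeps repeated composition and rendering
exactly reproducible.

Tracked correspondences contain outliers (instrument motion, specular
highlights, locally wrong flow), so per-transition estimation runs RANSAC
over 4-point DLT samples: 2000 iterations, 3 px reprojection inlier
threshold, minimum consensus 10, fixed seed. The consensus set is refit
by DLT and the inlier mask recomputed under the refit transform, so every
reported inlier satisfies the threshold by construction. When RANSAC
cannot form a consensus but at least 4 tracks survive, a least-squares
affine fit (6 dof) is tried as a fallback — with very few points a full
projective fit is underdetermined in practice.

### Feature detection

Shi–Tomasi corners: per pixel, the structure tensor of image gradients is
summed over an odd square window (uniform weights, 5×5 default) and the
score is the closed-form minimum eigenvalue. Gradients are 3×3 Sobel
scaled by 1/8 (unit ramp → unit gradient); pixels whose window leaves the
image score 0. Detection thresholds at `quality_level` (default 0.01) of
the global maximum and applies greedy minimum-distance non-maximum
suppression (default 8 px) in descending score order, ties broken by
ascending (y, x), truncated to `max_corners` (400). Integer pixel maxima
are returned without sub-pixel refinement — Lucas–Kanade immediately
refines positions anyway. On fundus scenes the score concentrates along
vessel edges and bifurcations, which is why tracked points cluster on the
vascular tree.

### Optical flow

Iterative pyramidal Lucas–Kanade. The pyramid blurs with the 5-tap
binomial kernel [1,4,6,4,1]/16 (separable, edge replication) and
decimates to even rows/columns; 3 levels by default. Per point and level,
the displacement is refined by d ← d + G⁻¹b where G is the window's
gradient tensor of the first frame (central differences, sampled
bilinearly, constant within a level's iterations — the Bouguet scheme)
and b the gradient-weighted temporal difference; iteration stops when the
update norm falls below ε = 0.01 px or after 30 iterations. Window radius
is 10 (21×21). Out-of-image window samples clamp to the edge. Statuses:

* `ill_conditioned` — λ_min(G)/window area below 1e−4 at the finest level
  (textureless patch);
* `lost_bounds` — the point leaves the image;
* `diverged` — no convergence at the finest level with a last step above
  0.5 px;
* `fb_failed` — the forward–backward check: each point is re-tracked from
  the second frame back to the first and rejected when the round trip
  misses its origin by more than 1 px. This check is the package's
  operational definition of a "successfully matched" point.

The implementation is vectorized across points (all windows sampled as a
single (n, 441) gather per iteration), which is what keeps a 200-frame
sequence tractable on one CPU core.

### Transition success and failure handling

A transition succeeds when ≥ `min_tracks_for_update` (25) verified tracks
survive and the robust fit keeps an inlier fraction ≥ 0.5. On success the
cumulative transform is composed; on failure the default `hold_last`
policy freezes the overlay (a frozen overlay is clinically safer than a
jumping one) and tracking resumes from the last successfully aligned
frame, so one corrupt frame costs exactly one transition. A perfectly
static transition (all displacements exactly zero) short-circuits to the
exact identity transform rather than a numerically-near-identity DLT
estimate, making repeated frames render bit-identically.

### Rendering

Inverse warping: each output pixel inside the warped map support samples
the pseudocolored map bilinearly at H⁻¹(p) and is alpha-blended (α = 0.4
default) with the frame; outside the support the frame passes through.
The pseudocolor is a fixed 256-entry piecewise-linear lookup table
through clinical-style thickness colors (blue → green → yellow → red →
white), shipped with the package so renders are bit-reproducible; a
scalar is quantized to the LUT index by rounding (no interpolation
between entries).

## Synthetic ground truth

Real membrane-peeling recordings are not distributable, so correctness is
established on phantoms with exact ground truth:

* **Scene** — a 320×240 canvas (a scaled-down stand-in for the WSVGA
  surgical video this pipeline targets) with a circular illuminated field
  of view (radius 0.45·min dimension, 3 px feathered rim, exactly black
  outside), warm smooth background texture, Gaussian pixel noise
  (σ = 0.02), and a dark vascular tree grown recursively from a seeded
  disc location: 5 trunks, 4 branching generations, widths decaying by
  0.75 per generation from 3.5 px. The vessel mask is exact (true where
  the rasterized centerline distance is within the half-width). Seed-0
  vessel coverage is ~0.10 of the FOV area.
* **Motion** — per-frame increments of translation, rotation, log-scale
  and perspective jitter follow an AR(1) process (coefficient 0.8) with
  innovation SDs (0.4 px, 1.5e−3 rad, 8e−4, 2e−6), composed about the
  image center; chosen once as plausible smooth surgeon/eye motion at
  this scale. Frame k is the master frame inverse-warped through the
  cumulative ground-truth transform — motion by warping a single master
  guarantees exact ground truth at the cost of slight interpolation
  softening, which sits well below the tracker's tolerances.
* **Degradations** — a dark instrument shaft anchored at the field edge
  whose tip sweeps a seeded linear path (drawn after warping: the
  instrument moves independently of the retina), optional Gaussian blur
  and multiplicative illumination drift.
* **Thickness map** — a base plane plus seeded anisotropic Gaussian bumps
  (σ ≥ 15 px), rescaled to [0, 1]; registered to frame 0 (identity map
  transform by default) with five well-spread landmark pairs generated
  consistently with that transform.

Every dataset is a pure function of its manifest; regeneration is
bit-identical.

**What the phantom does not emulate:** non-planar retinal curvature and
instrument parallax, specular reflections, dye staining, depth-of-field
and motion blur of real optics, rolling-shutter effects, illumination
flicker beyond a smooth drift, and re-rendered (rather than warped)
scene appearance. Passing the phantom suite therefore demonstrates the
geometric and numerical correctness of the pipeline and its failure
handling — not clinical-grade performance on surgical video, whose
success rates must be established on real recordings.

## Problem sizes and budgets

Defaults used throughout the tests and the acceptance script: 320×240
frames, 200-frame clean sequences, 100-frame occluded sequences, 400
corners per frame, 256×256 textures for flow recovery. These sizes were
chosen so the whole verification suite runs in minutes on a single core
while leaving every algorithmic parameter at its full-scale default.

## Known limitations

* Forward chaining accumulates drift without bound; there is no keyframe
  re-anchoring to frame 0 (measured drift on the clean 200-frame phantom
  is below 2 px, but hour-long sequences would need re-anchoring or
  periodic re-initialization).
* The transform model is a single global homography; instrument parallax
  is handled only statistically, by RANSAC rejecting instrument tracks.
* Landmarks come from a file; there is no interactive picking UI.
* Illumination changes are not modelled in the LK objective (no gain or
  bias compensation); strong flicker degrades tracking before geometry
  does.
* The per-frame corner re-detection (rather than track reuse) follows the
  published pipeline description; it is the dominant per-frame cost.
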