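# octoverlay

Real-time registration of preoperative OCT retinal thickness maps onto
vitreoretinal surgical video.

During epiretinal membrane peeling, the surgeon's structural reference —
the OCT thickness map — lives in a different coordinate frame than the
live microscope view. `octoverlay` aligns the map with the video once,
from a handful of manually selected landmark correspondences, and then
keeps it aligned automatically: a translucent pseudocolor overlay that
follows the retina through eye and camera motion. It is aimed at
surgical image-analysis researchers prototyping augmented-reality
overlays from standard recorded video, without intraoperative OCT
hardware.

## Method

The retina is modelled as a plane, so views are related by homographies
**H** acting on homogeneous pixel coordinates [x, y, 1]ᵀ:

1. **Initialization** — ≥4 (typically 5) landmark pairs between the map
   and frame 0 give **H₀** (map → frame 0) by Hartley-normalized DLT.
2. **Frame-to-frame tracking** — Shi–Tomasi corners (windowed
   minimum-eigenvalue score) detected on each frame are tracked into the
   next with iterative pyramidal Lucas–Kanade flow; a forward–backward
   round-trip check discards unreliable tracks.
3. **Robust update** — RANSAC over 4-point DLT samples fits the
   transition **Tₖ** (frame k−1 → frame k) to the surviving tracks.
4. **Chaining** — the cumulative alignment is **Hₖ = Tₖ·Hₖ₋₁**; the map
   is rendered into every frame by inverse warping with bilinear
   sampling and alpha blending.
5. **Failure handling** — a transition with too few verified tracks or
   too low an inlier ratio freezes the overlay (`hold_last`) and
   tracking resumes from the last successfully aligned frame.

Because surgical recordings cannot be redistributed, the package ships a
synthetic fundus generator (circular field of view, branching vascular
tree, smooth AR(1) homographic motion, instrument-shaft occluder) with
exact per-frame ground-truth transforms, so every stage is verifiable
end to end. See `docs/methods.md` for the full model description.

## Worked example

Simulate a 60-frame phantom sequence, then track it:

```sh
octoverlay simulate --out demo --seed 3 --frames 60
octoverlay track --frames demo/frames --map demo/map.png \
    --landmarks demo/landmarks.csv --out demo/overlay --report demo/report.json
```

which prints:

```
wrote 60 frames; frame-0 corners near vessels: 72.2%
tracked 60 frames, success rate 100.0% (4.96 FPS, informational)
```

`demo/overlay/` now holds the overlaid frames and `demo/report.json` the
per-transition diagnostics: for each transition, how many corners were
detected, how many tracks survived the forward–backward check, how many
were RANSAC inliers, and whether the alignment update succeeded. The
"corners near vessels" figure is the fraction of detected feature points
within 5 px of the vascular tree — on fundus-like scenes the detector
naturally concentrates on vessels, which is what makes the tracking
robust. The same run is available from Python:

```python
import octoverlay as ov

ds = ov.generate_dataset(ov.PhantomParams(seed=3),
                         ov.MotionParams(n_frames=60, seed=4))
overlays, report = ov.run_sequence(ds.frames, ds.thickness_map, ds.landmarks)
print(ov.success_rate(report))   # 100.0
```

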