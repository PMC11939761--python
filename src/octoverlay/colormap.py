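"""Fixed pseudocolor lookup table for thickness-map rendering.

Retinal thickness maps are conventionally displayed on a blue-to-red ramp
(thin = blue, thick = red/white).  The table below is a fixed 256-entry
piecewise-linear ramp through clinical-style control colors, shipped with
the package so renders are bit-reproducible across platforms: a scalar in
[0, 1] is quantized to an index by rounding and looked up directly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["thickness_lut", "apply_colormap"]

# (position, (r, g, b)) control points of the thickness ramp
_STOPS = [
    (0.00, (0.00, 0.00, 0.55)),
    (0.20, (0.00, 0.45, 0.95)),
    (0.40, (0.00, 0.75, 0.45)),
    (0.60, (0.85, 0.85, 0.00)),
    (0.80, (0.95, 0.35, 0.00)),
    (0.95, (0.90, 0.05, 0.05)),
    (1.00, (1.00, 1.00, 1.00)),
]


def thickness_lut() -> np.ndarray:
    """The 256 x 3 float RGB lookup table for the thickness pseudocolor ramp."""
    pos = np.array([p for p, _ in _STOPS])
    cols = np.array([c for _, c in _STOPS])
    x = np.linspace(0.0, 1.0, 256)
    lut = np.stack([np.interp(x, pos, cols[:, c]) for c in range(3)], axis=1)
    return lut


_LUT = thickness_lut()


def apply_colormap(values: np.ndarray, name: str = "thickness_pseudocolor") -> np.ndarray:
    """Map a scalar image in [0, 1] to float RGB.

    ``thickness_pseudocolor`` uses the fixed ramp above; ``grayscale``
    replicates the scalar across channels.
    """
    v = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
    if name == "grayscale":
        return np.repeat(v[..., None], 3, axis=-1)
    if name == "thickness_pseudocolor":
        idx = np.rint(v * 255.0).astype(np.int64)
        return _LUT[idx]
    raise ValueError(f"unknown colormap {name!r}")
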