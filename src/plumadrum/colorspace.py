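"""Colour-space conversion and colour distances.

All colour computation in the package goes through this module: 8-bit sRGB
input, CIE 1976 L*a*b* under the D65 white point and 2° standard observer,
and plain Euclidean (CIE76) ΔE distances.  The chromatic distance uses the
opponent (a, b) plane only; the achromatic distance is |ΔL|.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from skimage import color as _skcolor


class RGBColor(NamedTuple):
    """An 8-bit sRGB colour; each channel in [0, 255]."""

    r: int
    g: int
    b: int


class LabColor(NamedTuple):
    """A CIE L*a*b* colour (D65, 2° observer); L in [0, 100]."""

    L: float
    a: float
    b: float


def rgb_array_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert an array of 8-bit sRGB triples (..., 3) to Lab floats.

    Accepts uint8 or float values on the 0–255 scale.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected trailing dimension of 3 (r, g, b)")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("sRGB channel values must lie in [0, 255]")
    return _skcolor.rgb2lab(arr / 255.0)


def lab_array_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Convert Lab triples to 8-bit sRGB (uint8), clipping out-of-gamut."""
    arr = np.asarray(lab, dtype=float)
    rgb = np.clip(_skcolor.lab2rgb(arr), 0.0, 1.0)
    return np.round(rgb * 255.0).astype(np.uint8)


def srgb_to_lab(c: RGBColor | tuple[int, int, int]) -> LabColor:
    """Convert a single 8-bit sRGB colour to CIE Lab (D65, 2° observer).

    Raises ``ValueError`` for channels outside [0, 255].
    """
    r, g, b = c
    for v in (r, g, b):
        if not (0 <= v <= 255):
            raise ValueError(f"sRGB channel {v!r} outside [0, 255]")
    lab = rgb_array_to_lab(np.array([[float(r), float(g), float(b)]]))[0]
    return LabColor(float(lab[0]), float(lab[1]), float(lab[2]))


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def delta_e(x, y):
    """CIE76 ΔE: Euclidean distance over (L, a, b).

    Works element-wise on arrays of shape (..., 3); returns a scalar for a
    single pair of colours.
    """
    xa, ya = _pair(x, y)
    d = np.sqrt(((xa - ya) ** 2).sum(axis=-1))
    return float(d) if d.ndim == 0 else d


def chromatic_distance(x, y):
    """Euclidean distance over the opponent (a, b) plane only."""
    xa, ya = _pair(x, y)
    d = np.sqrt(((xa[..., 1:] - ya[..., 1:]) ** 2).sum(axis=-1))
    return float(d) if d.ndim == 0 else d


def achromatic_distance(x, y):
    """Absolute lightness difference |ΔL|."""
    xa, ya = _pair(x, y)
    d = np.abs(xa[..., 0] - ya[..., 0])
    return float(d) if d.ndim == 0 else d


def pairwise_delta_e(palette: np.ndarray) -> np.ndarray:
    """Full symmetric ΔE matrix for a (k, 3) Lab palette."""
    p = np.asarray(palette, dtype=float)
    return np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(axis=-1))
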