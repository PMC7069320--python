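"""Photograph calibration and the RGB-derived 2-D color space.

Field photographs are taken under uncontrolled illumination with an in-frame
gray standard of known reflectance (18% by default).  Calibration proceeds in
two steps:

1. **Linearization** — undo the camera tone curve.  A single gray standard
   cannot identify the full response curve, so a fixed inverse-gamma model is
   used: ``v_lin = v_raw ** gamma`` with ``gamma = 2.2`` by default
   (configurable), the standard sRGB-class approximation.
2. **Equalization** — per-channel multiplicative scaling so that the gray
   standard reads exactly its known reflectance in every channel:
   ``c_out = target * c_lin / g_lin``.

Calibrated channels live on a reflectance scale (dimensionless, >= 0).  From a
calibrated color the module computes brightness ``V = (R + G + B) / 3`` and the
2-D chromaticity coordinates

    x = (R - G) / (R + G + B),    y = (G - B) / (R + G + B),

with saturation ``S = sqrt(x**2 + y**2)`` (distance from the achromatic
origin) and hue ``H`` the angle of ``(x, y)``.

Hue convention: the textbook definition ``H = arctan(y / x)`` is
quadrant-ambiguous; greenish-gray colors have negative ``x``, so this module
uses the full-quadrant two-argument angle (``atan2`` style), in radians, range
``(-pi, pi]``.  An achromatic color (``x = y = 0``) has no hue: the scalar
:func:`hue` raises :class:`~camoquant.errors.UndefinedHueError`, while the
vectorised table path records NaN, so achromatic rows never silently bias
circular summaries.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    DomainError,
    UndefinedChromaticityError,
    UndefinedHueError,
)

__all__ = [
    "RawColor",
    "GrayStandardObservation",
    "CalibratedColor",
    "Chromaticity",
    "linearize",
    "equalize",
    "calibrate",
    "chromaticity",
    "saturation",
    "hue",
    "brightness",
    "color_metrics",
    "calibrate_table",
]

DEFAULT_GAMMA = 2.2
DEFAULT_GRAY_REFLECTANCE = 0.18


class RawColor(NamedTuple):
    """Camera-encoded per-channel means, each in [0, 1]."""

    R_raw: float
    G_raw: float
    B_raw: float


class GrayStandardObservation(NamedTuple):
    """Camera-encoded means of the gray card plus its known reflectance."""

    R_g: float
    G_g: float
    B_g: float
    reflectance_target: float = DEFAULT_GRAY_REFLECTANCE


class CalibratedColor(NamedTuple):
    """Linearized, equalized RGB on the reflectance scale."""

    R: float
    G: float
    B: float

    @property
    def V(self) -> float:
        """Brightness, the channel mean."""
        return (self.R + self.G + self.B) / 3.0


class Chromaticity(NamedTuple):
    """Position in the 2-D color space: (x, y) plus polar S and H."""

    x: float
    y: float
    S: float
    H: float


def linearize(raw_value, gamma: float = DEFAULT_GAMMA):
    """Invert the camera tone curve: ``raw ** gamma``.

    Accepts scalars or arrays in [0, 1]; ``gamma`` must be positive.
    Endpoints 0 and 1 are fixed points and the map is monotone.
    """
    if gamma <= 0:
        raise DomainError(f"gamma must be > 0, got {gamma}")
    v = np.asarray(raw_value, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise DomainError("raw channel values must lie in [0, 1]")
    out = v ** gamma
    return float(out) if np.isscalar(raw_value) or out.ndim == 0 else out


def equalize(linear_rgb, gray_linear_rgb,
             reflectance_target: float = DEFAULT_GRAY_REFLECTANCE):
    """Scale each channel so the gray standard maps to its known reflectance.

    ``c_out = reflectance_target * c_lin / g_lin`` per channel.  The gray
    observation itself maps exactly to ``(t, t, t)``.
    """
    if not (0 < reflectance_target < 1):
        raise DomainError(
            f"reflectance_target must be in (0, 1), got {reflectance_target}")
    c = np.asarray(linear_rgb, dtype=float)
    g = np.asarray(gray_linear_rgb, dtype=float)
    if np.any(g <= 0):
        raise CalibrationError(
            "gray standard has a non-positive linearized channel; "
            "cannot equalize")
    out = reflectance_target * c / g
    if c.ndim == 1 and c.shape == (3,):
        return CalibratedColor(*out)
    return out


def calibrate(raw_rgb, gray_raw_rgb,
              gamma: float = DEFAULT_GAMMA,
              reflectance_target: float = DEFAULT_GRAY_REFLECTANCE):
    """Full calibration: linearize color and gray, then equalize."""
    return equalize(linearize(raw_rgb, gamma), linearize(gray_raw_rgb, gamma),
                    reflectance_target)


def chromaticity(c) -> tuple:
    """Standardized channel differences ``(x, y)`` of a calibrated color.

    Invariant to scaling the color by any k > 0; undefined for a zero-sum
    color.
    """
    r, g, b = (float(v) for v in tuple(c)[:3])
    total = r + g + b
    if total <= 0:
        raise UndefinedChromaticityError(
            "chromaticity undefined for zero-sum color")
    return (r - g) / total, (g - b) / total


def saturation(x: float, y: float) -> float:
    """Distance from the achromatic origin in (x, y) space."""
    return math.hypot(x, y)


def hue(x: float, y: float) -> float:
    """Full-quadrant hue angle of (x, y), radians in (-pi, pi].

    Raises :class:`UndefinedHueError` at the achromatic origin.
    """
    if x == 0 and y == 0:
        raise UndefinedHueError("achromatic color has no hue")
    return math.atan2(y, x)


def brightness(c) -> float:
    """Brightness V = (R + G + B) / 3 of a calibrated color."""
    r, g, b = (float(v) for v in tuple(c)[:3])
    if r < 0 or g < 0 or b < 0:
        raise DomainError("calibrated channels must be >= 0")
    return (r + g + b) / 3.0


def color_metrics(c) -> Chromaticity:
    """Chromaticity, saturation and hue of a calibrated color in one call."""
    x, y = chromaticity(c)
    s = saturation(x, y)
    h = math.nan if s == 0 else hue(x, y)
    return Chromaticity(x, y, s, h)


def calibrate_table(df: pd.DataFrame,
                    gamma: float = DEFAULT_GAMMA,
                    reflectance_target: float = DEFAULT_GRAY_REFLECTANCE,
                    prefix: str = "") -> pd.DataFrame:
    """Vectorised calibration of a table of raw means.

    Expects columns ``{prefix}R_raw, G_raw, B_raw`` and
    ``R_gray, G_gray, B_gray``; returns a copy with
    ``{prefix}R, G, B, V, x, y, S, H`` appended.  Achromatic rows get NaN hue.
    """
    raw = df[[f"{prefix}R_raw", f"{prefix}G_raw", f"{prefix}B_raw"]].to_numpy(float)
    gray = df[["R_gray", "G_gray", "B_gray"]].to_numpy(float)
    cal = equalize(linearize(raw, gamma), linearize(gray, gamma),
                   reflectance_target)
    total = cal.sum(axis=1)
    if np.any(total <= 0):
        raise UndefinedChromaticityError(
            "zero-sum calibrated color in table; chromaticity undefined")
    x = (cal[:, 0] - cal[:, 1]) / total
    y = (cal[:, 1] - cal[:, 2]) / total
    s = np.hypot(x, y)
    h = np.where(s == 0, np.nan, np.arctan2(y, x))
    out = df.copy()
    for i, ch in enumerate("RGB"):
        out[f"{prefix}{ch}"] = cal[:, i]
    out[f"{prefix}V"] = total / 3.0
    out[f"{prefix}x"] = x
    out[f"{prefix}y"] = y
    out[f"{prefix}S"] = s
    out[f"{prefix}H"] = h
    return out
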