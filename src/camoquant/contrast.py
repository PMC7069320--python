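"""Background-matching contrast indices.

Two indices compare a body region against its habitat background, both
computed from calibrated (reflectance-scale) RGB.  Lower values mean better
background matching.

**Achromatic contrast** — signed relative brightness difference,

    (sum_s - sum_b) / (sum_s + sum_b),

where ``sum`` is R+G+B and subscripts s/b denote skink and background.  Range
[-1, 1]; negative means the animal is darker than its background.  The sign
is kept (it carries the darker/lighter direction); ``abs()`` of it is the
magnitude column used for "how well matched" analyses.

**Chromatic contrast** — Euclidean distance between the two colors'
RGB *proportion* triples (each channel divided by the channel sum, so the
triple sums to 1).  Brightness-invariant, symmetric, range [0, sqrt(2)], and
a genuine metric on the simplex.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import UndefinedContrastError

__all__ = [
    "ContrastPair",
    "proportions",
    "achromatic_contrast",
    "chromatic_contrast",
    "contrast_pair",
    "region_contrast_table",
    "table_contrasts",
]

BODY_REGIONS = ("dorsal", "ventral", "ventral_tail")


class ContrastPair(NamedTuple):
    """Contrast of one body region against its background."""

    region: str
    achromatic: float
    chromatic: float
    missing: bool = False


def _rgb(c) -> tuple:
    return tuple(float(v) for v in tuple(c)[:3])


def proportions(c):
    """RGB proportion triple R/(R+G+B), ... ; sums to 1."""
    r, g, b = _rgb(c)
    total = r + g + b
    if total <= 0:
        raise UndefinedContrastError("proportions undefined for zero-sum color")
    return (r / total, g / total, b / total)


def achromatic_contrast(s, b) -> float:
    """Signed relative brightness difference, in [-1, 1]."""
    ss = sum(_rgb(s))
    sb = sum(_rgb(b))
    if ss + sb <= 0:
        raise UndefinedContrastError(
            "achromatic contrast undefined for two all-zero colors")
    return (ss - sb) / (ss + sb)


def chromatic_contrast(s, b) -> float:
    """Euclidean distance between RGB proportion triples, in [0, sqrt(2)]."""
    ps = proportions(s)
    pb = proportions(b)
    return math.sqrt(sum((a - c) ** 2 for a, c in zip(ps, pb)))


def contrast_pair(region: str, skink, background) -> ContrastPair:
    """Both indices for one region/background pair."""
    return ContrastPair(region,
                        achromatic_contrast(skink, background),
                        chromatic_contrast(skink, background))


def table_contrasts(df: pd.DataFrame, regions=BODY_REGIONS,
                    background: str = "background") -> pd.DataFrame:
    """Vectorised contrasts for a table with ``{region}_{R,G,B}`` columns.

    Appends ``{region}_achromatic``, ``{region}_abs_achromatic`` and
    ``{region}_chromatic`` against the ``background_*`` columns.  Rows with
    missing channels get NaN contrasts.
    """
    out = df.copy()
    bg = df[[f"{background}_{ch}" for ch in "RGB"]].to_numpy(float)
    bg_sum = bg.sum(axis=1)
    bg_prop = bg / bg_sum[:, None]
    for reg in regions:
        cols = [f"{reg}_{ch}" for ch in "RGB"]
        if not all(c in df.columns for c in cols):
            continue
        s = df[cols].to_numpy(float)
        s_sum = s.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ach = (s_sum - bg_sum) / (s_sum + bg_sum)
            chrom = np.linalg.norm(s / s_sum[:, None] - bg_prop, axis=1)
        out[f"{reg}_achromatic"] = ach
        out[f"{reg}_abs_achromatic"] = np.abs(ach)
        out[f"{reg}_chromatic"] = chrom
    return out


def region_contrast_table(region_colors: dict, background,
                          regions=BODY_REGIONS) -> pd.DataFrame:
    """Contrasts of every body region against one background.

    ``region_colors`` maps region name -> calibrated RGB (or None for a
    missing region: the row is kept with NaN contrasts and ``missing=True``,
    never silently dropped — field datasets have dropped photos).
    """
    rows = []
    for region in regions:
        color = region_colors.get(region)
        if color is None or (hasattr(color, "__len__")
                             and any(v is None or (isinstance(v, float) and math.isnan(v))
                                     for v in tuple(color)[:3])):
            rows.append(ContrastPair(region, math.nan, math.nan, missing=True))
        else:
            rows.append(contrast_pair(region, color, background))
    df = pd.DataFrame(rows)
    df["abs_achromatic"] = df["achromatic"].abs()
    return df
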