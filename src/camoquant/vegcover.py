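"""Sectioned vegetation-cover score of a 1x1 m background photograph.

The habitat photo is partitioned into four sections (2x2 quadrants; for odd
dimensions the top/left blocks take the extra row/column).  Each section is
scored as the percentage of the *whole image* area that is vegetated within
that section, rounded half-up to the nearest multiple of 5 and capped at 25
(a fully vegetated quadrant is a quarter of the image).  Any nonzero
vegetation scores at least 5, the smallest nonzero step of the scale, and a
section with no vegetation scores 0.  The four section scores sum to the
final cover score out of 100.

Rounding to the 5% scale means the total can deviate from the true pixel
percentage by at most 2.5 points per section (10 overall); masks whose
section areas sit exactly on the 5% grid are recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["CoverScore", "section_cover", "total_cover", "section_slices"]

SECTION_SCORES = (0, 5, 10, 15, 20, 25)


@dataclass(frozen=True)
class CoverScore:
    """Four section scores (percent, multiples of 5) and their total."""

    section_scores: tuple
    total: int


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2 or m.size == 0:
        raise DomainError("cover mask must be a nonempty 2-D raster")
    return m.astype(bool)


def section_slices(shape):
    """The four (row, col) slice pairs of the 2x2 partition, in reading order."""
    h, w = shape
    rh, cw = (h + 1) // 2, (w + 1) // 2
    return [(slice(0, rh), slice(0, cw)),
            (slice(0, rh), slice(cw, w)),
            (slice(rh, h), slice(0, cw)),
            (slice(rh, h), slice(cw, w))]


def section_cover(mask, section_index: int) -> int:
    """Score of one section: percent of whole-image area, on the 5% scale."""
    m = _as_mask(mask)
    if section_index not in (0, 1, 2, 3):
        raise DomainError(f"section_index must be 0..3, got {section_index}")
    rs, cs = section_slices(m.shape)[section_index]
    count = int(m[rs, cs].sum())
    if count == 0:
        return 0
    pct = 100.0 * count / m.size
    score = 5 * int(np.floor(pct / 5.0 + 0.5))  # round half-up to 5% steps
    return int(min(25, max(5, score)))


def total_cover(mask) -> CoverScore:
    """Sum of the four section scores: the final cover score out of 100."""
    scores = tuple(section_cover(mask, i) for i in range(4))
    return CoverScore(scores, int(sum(scores)))
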