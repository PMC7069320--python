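"""Rule-based classification of dorsal pattern types.

Shore-skink dorsal patterning falls into four discrete types combining two
binary features — dense dark speckling and a mid-dorsal longitudinal line
running along more than half the body:

======== ================ ====================
type     dense speckling  mid-dorsal line >50%
======== ================ ====================
plain    no               no
midplain no               yes
spot     yes              no
midspot  yes              yes
======== ================ ====================

The by-eye judgement is operationalized deterministically on a
:class:`BodyPatternMap`: binary rasters of the body, its dark speckles and
its mid-dorsal line, with the body axis aligned horizontally (raster columns
are axis positions).  "Dense" means the speckle fraction of body area is at
least ``dense_threshold`` (default 0.10 — a configurable operationalization,
not a recovered field parameter); the midline rule is strict ("more than
50%"), so coverage exactly 0.5 is not lined.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import DomainError

__all__ = ["PatternType", "BodyPatternMap", "midline_coverage",
           "speckle_score", "classify_pattern",
           "DEFAULT_DENSE_THRESHOLD", "DEFAULT_MIDLINE_THRESHOLD"]

DEFAULT_DENSE_THRESHOLD = 0.10
DEFAULT_MIDLINE_THRESHOLD = 0.5


class PatternType(str, Enum):
    plain = "plain"
    midplain = "midplain"
    spot = "spot"
    midspot = "midspot"


@dataclass(frozen=True)
class BodyPatternMap:
    """Binary rasters of body, speckles and midline (axis horizontal)."""

    body_mask: np.ndarray
    speckle_mask: np.ndarray
    midline_mask: np.ndarray

    def __post_init__(self):
        body = np.asarray(self.body_mask, bool)
        spk = np.asarray(self.speckle_mask, bool)
        mid = np.asarray(self.midline_mask, bool)
        if body.shape != spk.shape or body.shape != mid.shape:
            raise DomainError("pattern masks must share one shape")
        if not body.any():
            raise DomainError("empty body mask")
        if (spk & ~body).any():
            raise DomainError("speckle mask must be a subset of the body mask")
        if (mid & ~body).any():
            raise DomainError("midline mask must be a subset of the body mask")
        object.__setattr__(self, "body_mask", body)
        object.__setattr__(self, "speckle_mask", spk)
        object.__setattr__(self, "midline_mask", mid)

    @property
    def axis_length(self) -> int:
        """Number of raster columns occupied by the body."""
        return int(self.body_mask.any(axis=0).sum())


def midline_coverage(pmap: BodyPatternMap) -> float:
    """Fraction of body-axis columns at which the midline has >= 1 pixel."""
    body_cols = pmap.body_mask.any(axis=0)
    mid_cols = pmap.midline_mask.any(axis=0)
    return float((mid_cols & body_cols).sum() / body_cols.sum())


def speckle_score(pmap: BodyPatternMap) -> float:
    """Speckle pixels as a fraction of body pixels."""
    return float(pmap.speckle_mask.sum() / pmap.body_mask.sum())


def classify_pattern(pmap: BodyPatternMap,
                     dense_threshold: float = DEFAULT_DENSE_THRESHOLD,
                     midline_threshold: float = DEFAULT_MIDLINE_THRESHOLD
                     ) -> PatternType:
    """Assign one of the four pattern types by the 2x2 feature rule.

    Speckling is "dense" when ``speckle_score >= dense_threshold``; the
    midline counts when coverage is strictly greater than
    ``midline_threshold``.
    """
    dense = speckle_score(pmap) >= dense_threshold
    lined = midline_coverage(pmap) > midline_threshold
    if dense:
        return PatternType.midspot if lined else PatternType.spot
    return PatternType.midplain if lined else PatternType.plain
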