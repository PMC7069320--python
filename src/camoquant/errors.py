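"""Exception hierarchy for camoquant.

Every domain error raised by the library derives from :class:`CamoquantError`
so callers can catch pipeline failures in one place while still
distinguishing the specific failure mode.
"""


class CamoquantError(Exception):
    """Base class for all camoquant domain errors."""


class DomainError(CamoquantError, ValueError):
    """An input value lies outside the documented domain of an operation."""


class CalibrationError(CamoquantError, ValueError):
    """Gray-standard observation unusable (non-positive channel)."""


class UndefinedChromaticityError(CamoquantError, ValueError):
    """Chromaticity is undefined for a color with zero channel sum."""


class UndefinedHueError(CamoquantError, ValueError):
    """Hue is undefined for an achromatic color (x = y = 0)."""


class UndefinedContrastError(CamoquantError, ValueError):
    """Contrast is undefined (both colors all-zero, or a zero-sum color)."""


class EmptyROIError(CamoquantError, ValueError):
    """A polygon ROI contains no interior pixel centers."""


class InvalidROIError(CamoquantError, ValueError):
    """A polygon ROI violates its invariants (too few vertices, zero area,
    out-of-bounds vertices or self-intersection)."""


class DegenerateDataError(CamoquantError, ValueError):
    """A statistical routine received data with no usable variation."""


class MissingRegionError(CamoquantError, KeyError):
    """A required body region or background color is absent from a record."""
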