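"""Random-point color extraction from polygon ROIs.

Region mean colors are estimated from ``n`` random points (default 400) drawn
uniformly, with replacement, over the pixels whose centers fall inside the
region polygon.  The conventions are fixed bit-exactly so results are
reproducible across platforms:

* coordinates are 0-based ``(col, row)`` pixel indices; pixel centers sit at
  integer coordinates;
* containment is decided by the even-odd (ray crossing) rule applied to pixel
  centers;
* sampling is with replacement from the interior-pixel set, driven by a
  NumPy ``default_rng`` seeded by the caller.

:func:`full_region_mean` is the exhaustive counterpart (mean over every
interior pixel) and serves as the oracle the sampler converges to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EmptyROIError, InvalidROIError

__all__ = [
    "PolygonROI",
    "RegionSample",
    "ROI_LABELS",
    "interior_pixels",
    "sample_points",
    "region_mean_color",
    "full_region_mean",
    "background_mean",
    "load_rois",
    "save_rois",
    "rect_roi",
]

ROI_LABELS = ("dorsal", "ventral", "ventral_tail",
              "background_1", "background_2", "gray_standard")


@dataclass(frozen=True)
class PolygonROI:
    """A labelled polygon region in image coordinates.

    ``vertices`` is an ordered sequence of ``(col, row)`` pairs, 0-based.
    """

    label: str
    vertices: tuple

    def __init__(self, label: str, vertices: Sequence) -> None:
        object.__setattr__(self, "label", label)
        object.__setattr__(
            self, "vertices",
            tuple((float(c), float(r)) for c, r in vertices))
        if len(self.vertices) < 3:
            raise InvalidROIError(
                f"ROI '{label}': needs >= 3 vertices, got {len(self.vertices)}")
        if abs(self.signed_area()) <= 0:
            raise InvalidROIError(f"ROI '{label}': zero area")

    def signed_area(self) -> float:
        v = np.asarray(self.vertices)
        x, y = v[:, 0], v[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def within_bounds(self, image_shape) -> bool:
        h, w = image_shape[:2]
        v = np.asarray(self.vertices)
        return bool(np.all(v[:, 0] >= -0.5) and np.all(v[:, 0] <= w - 0.5)
                    and np.all(v[:, 1] >= -0.5) and np.all(v[:, 1] <= h - 0.5))

    def is_simple(self) -> bool:
        """Brute-force check that no two non-adjacent edges cross."""
        v = np.asarray(self.vertices)
        k = len(v)
        edges = [(v[i], v[(i + 1) % k]) for i in range(k)]

        def crosses(a, b, c, d):
            def orient(p, q, r):
                return np.sign((q[0] - p[0]) * (r[1] - p[1])
                               - (q[1] - p[1]) * (r[0] - p[0]))
            return (orient(a, b, c) * orient(a, b, d) < 0
                    and orient(c, d, a) * orient(c, d, b) < 0)

        for i in range(k):
            for j in range(i + 1, k):
                if j == i or (j + 1) % k == i or (i + 1) % k == j:
                    continue
                if crosses(*edges[i], *edges[j]):
                    return False
        return True


@dataclass(frozen=True)
class RegionSample:
    """Result of sampling one ROI: points, per-channel mean, count."""

    points: np.ndarray
    mean_rgb: tuple
    n: int = field(default=0)


def _interior_mask(vertices, image_shape):
    """Boolean mask of pixels whose centers lie inside the polygon (even-odd)."""
    h, w = image_shape[:2]
    v = np.asarray(vertices, dtype=float)
    cmin = max(0, int(np.floor(v[:, 0].min())))
    cmax = min(w - 1, int(np.ceil(v[:, 0].max())))
    rmin = max(0, int(np.floor(v[:, 1].min())))
    rmax = min(h - 1, int(np.ceil(v[:, 1].max())))
    if cmin > cmax or rmin > rmax:
        return np.zeros((0,), bool), np.zeros((0, 2), int)
    cols, rows = np.meshgrid(np.arange(cmin, cmax + 1),
                             np.arange(rmin, rmax + 1))
    px = cols.ravel().astype(float)
    py = rows.ravel().astype(float)
    inside = np.zeros(px.shape, dtype=bool)
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    # even-odd ray cast: horizontal ray towards +x from each pixel center
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:
            continue
        cond = (ey1 > py) != (ey2 > py)
        xint = ex1 + (py - ey1) * (ex2 - ex1) / (ey2 - ey1)
        inside ^= cond & (px < xint)
    pts = np.stack([px[inside], py[inside]], axis=1).astype(int)
    return inside, pts


def interior_pixels(roi: PolygonROI, image_shape) -> np.ndarray:
    """(k, 2) array of interior (col, row) pixel centers; raises if empty."""
    _, pts = _interior_mask(roi.vertices, image_shape)
    if len(pts) == 0:
        raise EmptyROIError(f"ROI '{roi.label}' has no interior pixel centers")
    return pts


def sample_points(roi: PolygonROI, image_shape, n: int, seed) -> np.ndarray:
    """Draw ``n`` interior pixel centers uniformly with replacement."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    pts = interior_pixels(roi, image_shape)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pts), size=n)
    return pts[idx]


def _pixel_values(image: np.ndarray, pts: np.ndarray) -> np.ndarray:
    vals = image[pts[:, 1], pts[:, 0]].astype(float)
    if image.dtype == np.uint8:
        vals = vals / 255.0
    elif image.dtype == np.uint16:
        vals = vals / 65535.0
    return vals


def region_mean_color(image: np.ndarray, roi: PolygonROI,
                      n: int = 400, seed=None) -> np.ndarray:
    """Per-channel mean over ``n`` random points, rescaled to [0, 1]."""
    pts = sample_points(roi, image.shape, n, seed)
    return _pixel_values(image, pts).mean(axis=0)


def full_region_mean(image: np.ndarray, roi: PolygonROI) -> np.ndarray:
    """Exact per-channel mean over every interior pixel (sampler oracle)."""
    pts = interior_pixels(roi, image.shape)
    return _pixel_values(image, pts).mean(axis=0)


def background_mean(image: np.ndarray, roi_1: PolygonROI, roi_2: PolygonROI,
                    n: int = 400, seed=None) -> np.ndarray:
    """Unweighted mean of the two background-region sampled means.

    Each ROI gets its own child stream of ``seed`` (spawn order: roi_1 then
    roi_2), so ``roi_1 == roi_2`` still yields two independent draws whose
    average estimates the same mean.
    """
    s1, s2 = np.random.SeedSequence(seed).spawn(2)
    m1 = region_mean_color(image, roi_1, n, s1)
    m2 = region_mean_color(image, roi_2, n, s2)
    return (m1 + m2) / 2.0


def rect_roi(label: str, c0: int, r0: int, c1: int, r1: int) -> PolygonROI:
    """Axis-aligned rectangle covering pixel centers c0..c1, r0..r1 inclusive.

    Edges sit at half-integer coordinates so no pixel center is ever on the
    boundary.
    """
    return PolygonROI(label, [(c0 - 0.5, r0 - 0.5), (c1 + 0.5, r0 - 0.5),
                              (c1 + 0.5, r1 + 0.5), (c0 - 0.5, r1 + 0.5)])


def load_rois(path) -> dict:
    """Read a per-image ROI JSON: {"image": ..., "rois": [{label, vertices}]}.

    Returns {label: PolygonROI}.
    """
    with open(path) as fh:
        doc = json.load(fh)
    rois = {}
    for entry in doc["rois"]:
        roi = PolygonROI(entry["label"], entry["vertices"])
        rois[roi.label] = roi
    return rois


def save_rois(path, image_name: str, rois: dict) -> None:
    doc = {"image": image_name,
           "rois": [{"label": r.label,
                     "vertices": [list(v) for v in r.vertices]}
                    for r in rois.values()]}
    Path(path).write_text(json.dumps(doc, indent=1))
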