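"""Synthetic scenes and populations with known ground truth.

Every stage of the pipeline is testable without any field download because
this module renders what the field protocol photographs — a habitat patch
with a vegetation gradient, skink body regions, and an in-frame 18% gray
standard — through an explicit camera model, and simulates population tables
with the statistical structure the analysis assumes.

**Camera model** (the simplest model the calibration can exactly invert):
per-channel gain, gamma compression (exponent ``1/gamma``), additive Gaussian
pixel noise on the encoded value, then 8-bit quantization.

**Color parameterisation.**  Region colors are specified as
``(V, x, y)`` — brightness plus the 2-D chromaticity — and converted to
reflectance RGB by inverting the chromaticity formulas:

    G = T (1 - x + y) / 3,  R = G + xT,  B = G - yT,   with T = 3V.

**Population structure** (defaults emulate the reported directions):

* background brightness declines steeply with vegetation cover; dorsal skink
  brightness declines too, but far more weakly, so skinks are slightly darker
  than their background on bare sand and lighter than it in dense vegetation;
* background chromaticity drifts green-ward with cover while dorsal
  chromaticity stays put, so the expected dorsal chromatic contrast is linear
  in cover with a known generating slope (``chromatic_slope``);
* ventral and ventral-tail regions are paler and orange-brown; ventral
  saturation is higher in adults than juveniles and higher again in adult
  males; adult-male tails are redder;
* dorsal hue shifts seasonally (greenest in the nonbreeding season) and
  tracks cover during the nonbreeding/mating seasons only;
* pattern-type frequencies follow the observed population mix and complexity
  increases with cover;
* mass follows a cube-law allometry on snout–vent length with lognormal
  scatter (the basis of the scaled mass index).

All randomness flows from one top-level seed through named substreams, so
fixtures are bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import sampling, vegcover
from .errors import DomainError
from .patterns import BodyPatternMap
from .sampling import PolygonROI, rect_roi

__all__ = [
    "SceneParams", "SceneBundle", "PopulationParams",
    "render_scene", "generate_population", "scene_from_record",
    "make_pattern_map", "rgb_from_vxy", "vxy_from_rgb", "substream",
    "SEASONS", "REGIONS",
]

SEASONS = ("nb", "bm", "bb")
REGIONS = ("dorsal", "ventral", "ventral_tail")
PATTERNS = ("plain", "midplain", "spot", "midspot")

SCENE_SHAPE = (100, 150)          # rows, cols
HABITAT = (slice(0, 100), slice(0, 100))   # 100x100 habitat photo region
PATCHES = {                        # inclusive pixel boxes (c0, r0, c1, r1)
    "dorsal": (105, 5, 125, 45),
    "ventral": (105, 55, 125, 75),
    "ventral_tail": (105, 82, 125, 96),
    "gray_standard": (130, 5, 147, 30),
}
BACKGROUND_BOXES = {"background_1": (5, 10, 45, 40),
                    "background_2": (55, 60, 95, 90)}


def substream(seed, name: str) -> np.random.Generator:
    """Named, platform-stable child RNG of a top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))


def rgb_from_vxy(v: float, x: float, y: float) -> np.ndarray:
    """Reflectance RGB with brightness ``v`` and chromaticity ``(x, y)``."""
    t = 3.0 * v
    g = t * (1.0 - x + y) / 3.0
    rgb = np.array([g + x * t, g, g - y * t])
    if np.any(rgb < 0):
        raise DomainError(f"(V={v}, x={x}, y={y}) leaves the RGB gamut")
    return rgb


def vxy_from_rgb(rgb) -> tuple:
    r, g, b = (float(c) for c in rgb)
    t = r + g + b
    return t / 3.0, (r - g) / t, (g - b) / t


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneParams:
    """Ground truth for one rendered scene."""

    vegetation_cover: float = 0.4          # true fraction in [0, 1]
    sand_rgb: tuple = (0.55, 0.50, 0.40)
    veg_rgb: tuple = (0.12, 0.20, 0.10)
    dorsal_rgb: tuple = (0.42, 0.40, 0.36)
    ventral_rgb: tuple = (0.58, 0.50, 0.40)
    ventral_tail_rgb: tuple = (0.62, 0.51, 0.40)
    speckle_fraction: float = 0.3
    midline_fraction: float = 0.8
    gains: tuple = (1.0, 1.0, 1.0)
    gamma: float = 2.2
    pixel_noise_sd: float = 0.0
    gray_reflectance: float = 0.18
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.vegetation_cover <= 1:
            raise DomainError("vegetation_cover must be in [0, 1]")
        if any(g <= 0 for g in self.gains):
            raise DomainError("camera gains must be positive")
        if self.pixel_noise_sd < 0:
            raise DomainError("pixel_noise_sd must be >= 0")


@dataclass(frozen=True)
class SceneBundle:
    """Rendered image plus everything the pipeline needs, with ground truth."""

    image: np.ndarray                       # uint8 RGB
    rois: dict                              # label -> PolygonROI
    vegetation_mask: np.ndarray             # bool, habitat photo region
    pattern_map: BodyPatternMap
    ground_truth: SceneParams
    true_region_rgb: dict                   # label -> reflectance triple


def _habitat_veg_mask(cover: float, shape=(100, 100)) -> np.ndarray:
    """Blocky vegetation mask aligned to the 5% grid.

    Cover is quantised to 5% units; each unit fills 10 consecutive rows of
    one 50x50 quadrant, so every section score is exact on the scoring grid.
    """
    h, w = shape
    mask = np.zeros(shape, bool)
    units = int(round(cover * 20))          # 0..20 units of 5%
    quads = vegcover.section_slices(shape)
    for q, (rs, cs) in enumerate(quads):
        take = min(5, units - 5 * q) if units > 5 * q else 0
        if take > 0:
            mask[rs.start:rs.start + 10 * take, cs] = True
    return mask


def make_pattern_map(speckle_fraction: float, midline_fraction: float,
                     seed, shape=(40, 200)) -> BodyPatternMap:
    """Axis-aligned body map with the requested speckle density and midline run.

    The body is an ellipse with horizontal major axis; speckles are an exact
    count of uniformly chosen body pixels; the midline is a 3-row central band
    running the requested fraction of body columns from the head end.
    """
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    body = (((cols - (w - 1) / 2) / (w / 2 - 1)) ** 2
            + ((rows - (h - 1) / 2) / (h / 2 - 1)) ** 2) <= 1.0
    rng = substream(seed, "pattern")
    n_body = int(body.sum())
    n_spk = int(round(speckle_fraction * n_body))
    spk = np.zeros_like(body)
    if n_spk > 0:
        flat = np.flatnonzero(body)
        chosen = rng.choice(flat, size=n_spk, replace=False)
        spk.ravel()[chosen] = True
    body_cols = np.flatnonzero(body.any(axis=0))
    n_mid = int(round(midline_fraction * len(body_cols)))
    mid = np.zeros_like(body)
    if n_mid > 0:
        mid_rows = slice(h // 2 - 1, h // 2 + 2)
        mid[mid_rows, body_cols[:n_mid]] = True
        mid &= body
    return BodyPatternMap(body, spk, mid)


def _encode(reflectance: np.ndarray, p: SceneParams,
            rng: np.random.Generator) -> np.ndarray:
    """Camera model: gain, gamma-compress, additive noise, 8-bit quantize."""
    lin = np.clip(reflectance * np.asarray(p.gains), 0.0, 1.0)
    enc = lin ** (1.0 / p.gamma)
    if p.pixel_noise_sd > 0:
        enc = enc + rng.normal(0.0, p.pixel_noise_sd, size=enc.shape)
    return np.clip(np.round(np.clip(enc, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)


def render_scene(p: SceneParams) -> SceneBundle:
    """Render one scene through the camera model; same seed, same image."""
    h, w = SCENE_SHAPE
    refl = np.empty((h, w, 3), float)
    refl[:] = 0.30                                   # neutral staging strip
    veg_mask = _habitat_veg_mask(p.vegetation_cover)
    hab = refl[HABITAT[0], HABITAT[1]]
    hab[:] = np.asarray(p.sand_rgb)
    hab[veg_mask] = np.asarray(p.veg_rgb)
    region_rgb = {"dorsal": p.dorsal_rgb, "ventral": p.ventral_rgb,
                  "ventral_tail": p.ventral_tail_rgb,
                  "gray_standard": (p.gray_reflectance,) * 3}
    rois = {}
    for label, (c0, r0, c1, r1) in PATCHES.items():
        if c1 >= w or r1 >= h:
            raise DomainError(f"patch '{label}' exceeds the frame")
        refl[r0:r1 + 1, c0:c1 + 1] = np.asarray(region_rgb[label])
        rois[label] = rect_roi(label, c0, r0, c1, r1)
    true_rgb = {k: tuple(float(v) for v in np.asarray(c))
                for k, c in region_rgb.items()}
    for label, (c0, r0, c1, r1) in BACKGROUND_BOXES.items():
        rois[label] = rect_roi(label, c0, r0, c1, r1)
        true_rgb[label] = tuple(
            refl[r0:r1 + 1, c0:c1 + 1].reshape(-1, 3).mean(axis=0))
    image = _encode(refl, p, substream(p.seed, "scene"))
    pmap = make_pattern_map(p.speckle_fraction, p.midline_fraction, p.seed)
    return SceneBundle(image=image, rois=rois, vegetation_mask=veg_mask,
                       pattern_map=pmap, ground_truth=p,
                       true_region_rgb=true_rgb)


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationParams:
    """Generating parameters of the simulated skink population.

    Brightness/chromaticity units match the calibrated reflectance scale;
    cover is the 0–100 percent score; slopes are per percentage point.
    """

    n: int = 352
    year_counts: tuple = ((2006, 19), (2007, 271), (2008, 62))
    season_probs: tuple = (0.40, 0.30, 0.30)        # nb, bm, bb
    adult_prob: float = 0.65
    male_prob: float = 0.5
    gravid_prob: float = 0.45                        # among adult females

    # brightness structure (V on the reflectance scale)
    background_v0: float = 0.45
    background_v_slope: float = -0.0030              # steep decline with cover
    background_v_sd: float = 0.02
    dorsal_v0: float = 0.42
    dorsal_v_slope: float = -0.0012                  # weaker tracking
    dorsal_v_sd: float = 0.03
    ventral_v0: float = 0.50
    ventral_v_sd: float = 0.03
    tail_v0: float = 0.52
    tail_v_sd: float = 0.03

    # dorsal chromaticity (gray-brown, low saturation)
    dorsal_sat: float = 0.05
    dorsal_sat_sd: float = 0.008
    dorsal_hue0: float = 0.30
    season_hue_offsets: tuple = (("nb", 0.25), ("bm", 0.05), ("bb", -0.20))
    hue_cover_slopes: tuple = (("nb", 0.004), ("bm", 0.002), ("bb", 0.0))
    hue_sd: float = 0.08

    # background chromatic offset from the dorsal base point, in RGB-proportion
    # space along the green-ward unit direction (-1, 1, 0)/sqrt(2):
    # E[dorsal chromatic contrast] = chromatic_d0 + chromatic_slope * cover
    chromatic_d0: float = 0.08
    chromatic_slope: float = 0.0008
    chromatic_sd: float = 0.02

    # ventral / tail chromaticity (orange-brown)
    ventral_sat0: float = 0.10
    ventral_sat_adult: float = 0.05                  # adult - juvenile
    ventral_sat_male: float = 0.03                   # adult male - adult female
    ventral_sat_season: tuple = (("nb", 0.02), ("bm", -0.01), ("bb", 0.0))
    ventral_sat_sd: float = 0.02
    ventral_hue0: float = 0.55
    ventral_hue_bm: float = 0.10                     # yellower in mating season
    tail_sat0: float = 0.14
    tail_hue0: float = 0.35
    tail_hue_male: float = -0.10                     # red-ward shift
    chroma_hue_sd: float = 0.06

    # allometry: ln mass = ln a + b ln SVL + eps
    allometry_a: float = 2.1e-5
    allometry_b: float = 3.0
    mass_log_sd: float = 0.08
    svl_adult_mean: float = 60.0
    svl_adult_sd: float = 5.0
    svl_juv_mean: float = 42.0
    svl_juv_sd: float = 4.0

    # pattern mix (plain, midplain, spot, midspot) and spatial structure
    pattern_base: tuple = (21 / 352, 67 / 352, 32 / 352, 232 / 352)
    pattern_structure: float = 1.2

    obs_noise_sd: float = 0.004                      # RGB measurement noise

    def __post_init__(self):
        if self.n < 0:
            raise DomainError("n must be >= 0")
        if abs(sum(self.season_probs) - 1) > 1e-9:
            raise DomainError("season_probs must sum to 1")


_GREEN_DIR = np.array([-1.0, 1.0, 0.0]) / np.sqrt(2.0)   # in proportion space

_COLOR_COLS = [f"{pfx}{reg}_{ch}"
               for pfx in ("true_", "")
               for reg in ("dorsal", "ventral", "ventral_tail", "background")
               for ch in "RGB"]


def _proportions_from_xy(x, y):
    g = (1.0 - x + y) / 3.0
    return np.stack([g + x, g, g - y], axis=-1)


def _lookup(pairs, keys):
    d = dict(pairs)
    return np.array([d[k] for k in keys])


def generate_population(p: PopulationParams, seed=0) -> pd.DataFrame:
    """Simulate the population table; one row per photographed individual."""
    n = p.n
    cols = (["id", "year", "season", "age", "sex", "gravid", "svl_mm",
             "mass_g", "vegetation_cover", "pattern", "speckle_fraction",
             "midline_fraction"] + _COLOR_COLS)
    if n == 0:
        return pd.DataFrame(columns=cols)

    rng = substream(seed, "population")
    years = np.repeat([y for y, _ in p.year_counts],
                      _counts(p.year_counts, n))
    season = rng.choice(SEASONS, size=n, p=p.season_probs)
    adult = rng.random(n) < p.adult_prob
    male = rng.random(n) < p.male_prob
    sex = np.where(male, "male", "female")
    gravid = (~male) & adult & (rng.random(n) < p.gravid_prob)
    cover = rng.integers(0, 21, size=n) * 5.0        # 0..100 on the 5% grid

    svl = np.where(adult,
                   rng.normal(p.svl_adult_mean, p.svl_adult_sd, n),
                   rng.normal(p.svl_juv_mean, p.svl_juv_sd, n))
    svl = np.clip(svl, 25.0, 75.0)
    mass = np.exp(np.log(p.allometry_a) + p.allometry_b * np.log(svl)
                  + rng.normal(0.0, p.mass_log_sd, n))

    # pattern types: complexity-weighted multinomial along the cover gradient
    complexity = np.array([-1.0, 0.0, 0.0, 1.0])
    logw = (np.log(np.asarray(p.pattern_base))[None, :]
            + p.pattern_structure * complexity[None, :]
            * ((cover[:, None] - 50.0) / 50.0))
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(n)
    pat_idx = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
    pattern = np.array(PATTERNS)[pat_idx]
    spk_lo = np.where(pat_idx >= 2, 0.25, 0.0)
    spk_hi = np.where(pat_idx >= 2, 0.60, 0.05)
    speckle = rng.uniform(spk_lo, spk_hi)
    lined = (pat_idx == 1) | (pat_idx == 3)
    midline = rng.uniform(np.where(lined, 0.65, 0.0),
                          np.where(lined, 0.95, 0.35))

    # dorsal color
    d_sat = np.clip(p.dorsal_sat + rng.normal(0, p.dorsal_sat_sd, n), 0.0, None)
    d_hue = (p.dorsal_hue0
             + _lookup(p.season_hue_offsets, season)
             + _lookup(p.hue_cover_slopes, season) * (cover - 50.0)
             + rng.normal(0, p.hue_sd, n))
    d_x, d_y = d_sat * np.cos(d_hue), d_sat * np.sin(d_hue)
    d_v = np.clip(p.dorsal_v0 + p.dorsal_v_slope * cover
                  + rng.normal(0, p.dorsal_v_sd, n), 0.05, None)

    # background: each individual's dorsal point pushed green-ward by a
    # cover-linear distance in proportion space, so the pair's expected
    # chromatic contrast is exactly chromatic_d0 + chromatic_slope * cover
    dorsal_prop = _proportions_from_xy(d_x, d_y)
    dist = np.clip(p.chromatic_d0 + p.chromatic_slope * cover
                   + rng.normal(0, p.chromatic_sd, n), 0.002, None)
    b_prop = dorsal_prop + dist[:, None] * _GREEN_DIR[None, :]
    b_v = np.clip(p.background_v0 + p.background_v_slope * cover
                  + rng.normal(0, p.background_v_sd, n), 0.05, None)
    b_rgb = b_prop * (3.0 * b_v)[:, None]

    # ventral and tail colors
    v_sat = np.clip(p.ventral_sat0
                    + p.ventral_sat_adult * adult
                    + p.ventral_sat_male * (adult & male)
                    + _lookup(p.ventral_sat_season, season)
                    + rng.normal(0, p.ventral_sat_sd, n), 0.0, None)
    v_hue = (p.ventral_hue0 + p.ventral_hue_bm * (season == "bm")
             + rng.normal(0, p.chroma_hue_sd, n))
    t_sat = np.clip(p.tail_sat0
                    + p.ventral_sat_adult * adult
                    + p.ventral_sat_male * (adult & male)
                    + rng.normal(0, p.ventral_sat_sd, n), 0.0, None)
    t_hue = (p.tail_hue0 + p.tail_hue_male * (adult & male)
             + rng.normal(0, p.chroma_hue_sd, n))
    v_v = np.clip(p.ventral_v0 + rng.normal(0, p.ventral_v_sd, n), 0.05, None)
    t_v = np.clip(p.tail_v0 + rng.normal(0, p.tail_v_sd, n), 0.05, None)

    true_rgb = {
        "dorsal": _rgb_stack(d_v, d_x, d_y),
        "ventral": _rgb_stack(v_v, v_sat * np.cos(v_hue), v_sat * np.sin(v_hue)),
        "ventral_tail": _rgb_stack(t_v, t_sat * np.cos(t_hue), t_sat * np.sin(t_hue)),
        "background": b_rgb,
    }
    df = pd.DataFrame({
        "id": [f"sk{i:04d}" for i in range(n)],
        "year": years, "season": season,
        "age": np.where(adult, "adult", "juvenile"), "sex": sex,
        "gravid": gravid, "svl_mm": svl, "mass_g": mass,
        "vegetation_cover": cover, "pattern": pattern,
        "speckle_fraction": speckle, "midline_fraction": midline,
    })
    obs_rng = substream(seed, "observation")
    for reg, rgb in true_rgb.items():
        obs = np.clip(rgb + obs_rng.normal(0, p.obs_noise_sd, rgb.shape),
                      1e-6, None)
        for j, ch in enumerate("RGB"):
            df[f"true_{reg}_{ch}"] = rgb[:, j]
            df[f"{reg}_{ch}"] = obs[:, j]
    return df


def _counts(year_counts, n):
    tot = sum(c for _, c in year_counts)
    raw = [c * n / tot for _, c in year_counts]
    out = [int(np.floor(r)) for r in raw]
    rem = n - sum(out)
    order = np.argsort([f - np.floor(f) for f in raw])[::-1]
    for i in order[:rem]:
        out[i] += 1
    return out


def _rgb_stack(v, x, y):
    t = 3.0 * v
    g = t * (1.0 - x + y) / 3.0
    rgb = np.stack([g + x * t, g, g - y * t], axis=1)
    return np.clip(rgb, 1e-6, None)


def scene_from_record(record, seed: Optional[int] = None,
                      gains=(1.0, 1.0, 1.0), gamma: float = 2.2,
                      pixel_noise_sd: float = 0.0) -> SceneBundle:
    """Render the scene implied by one population-table row.

    The habitat is painted uniformly with the record's true background
    reflectance (sand and vegetation share it) so the image pipeline's ROI
    means reproduce the tabular colors; the vegetation mask still follows the
    record's cover score for pattern/cover checks.
    """
    def true3(reg):
        try:
            return tuple(float(record[f"true_{reg}_{ch}"]) for ch in "RGB")
        except KeyError as exc:
            raise DomainError(f"record lacks true colors for '{reg}'") from exc

    bg = true3("background")
    params = SceneParams(
        vegetation_cover=float(record["vegetation_cover"]) / 100.0,
        sand_rgb=bg, veg_rgb=bg,
        dorsal_rgb=true3("dorsal"),
        ventral_rgb=true3("ventral"),
        ventral_tail_rgb=true3("ventral_tail"),
        speckle_fraction=float(record["speckle_fraction"]),
        midline_fraction=float(record["midline_fraction"]),
        gains=tuple(gains), gamma=gamma, pixel_noise_sd=pixel_noise_sd,
        seed=int(seed if seed is not None
                 else zlib.crc32(str(record["id"]).encode())),
    )
    return render_scene(params)
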