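"""Batch orchestration: configuration, extraction, analysis, validation.

``run_pipeline`` turns a directory of photographs + per-image ROI JSONs + a
metadata CSV into one record row per image (raw means → calibrated colors →
chromaticity/hue/saturation → contrasts), fully determined by (inputs,
config, seed).  A run manifest (config, seed, version, per-image status) is
written next to the records so every image is accounted for as processed or
skipped-with-reason; a missing gray standard skips the image with a logged
reason, while a malformed ROI file is a hard error naming the file.

``analyze_table`` runs the inferential battery on a records table: paired
signed-rank comparisons of the three body regions, contrast-vs-cover
regressions, Kruskal–Wallis + rank-sum spatial structure of pattern types,
AICc ranking of the candidate mixed models, Tukey contrasts for age/sex/
season, and a seasonal chromatic-contrast summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from . import colorcore, contrast, sampling, stats
from .errors import CamoquantError, InvalidROIError
from .sampling import ROI_LABELS

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs",
           "extract_record", "analyze_table", "seasonal_contrast_summary",
           "add_derived_columns", "DEFAULT_CANDIDATE_MODELS"]

log = logging.getLogger("camoquant")

DEFAULT_CANDIDATE_MODELS = (
    ("null", ()),
    ("cover", ("vegetation_cover",)),
    ("age", ("age",)),
    ("season", ("season",)),
    ("cover+age", ("vegetation_cover", "age")),
    ("cover+season", ("vegetation_cover", "season")),
    ("cover+age+season", ("vegetation_cover", "age", "season")),
    ("cover+age+season+pattern",
     ("vegetation_cover", "age", "season", "pattern")),
)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of a pipeline run; JSON round-trips exactly."""

    points_per_region: int = 400
    gamma: float = 2.2
    gray_reflectance: float = 0.18
    dense_threshold: float = 0.10
    midline_threshold: float = 0.5
    candidate_models: tuple = DEFAULT_CANDIDATE_MODELS
    seed: int = 0

    def __post_init__(self):
        if self.points_per_region < 1:
            raise CamoquantError("points_per_region must be >= 1")
        if self.gamma <= 0:
            raise CamoquantError("gamma must be > 0")
        if not 0 < self.gray_reflectance < 1:
            raise CamoquantError("gray_reflectance must be in (0, 1)")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["candidate_models"] = [[label, list(terms)]
                                 for label, terms in self.candidate_models]
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["candidate_models"] = tuple(
            (label, tuple(terms)) for label, terms in d["candidate_models"])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _roi_seed(base_seed: int, image_id: str, label: str) -> np.random.SeedSequence:
    import zlib
    return np.random.SeedSequence(
        [int(base_seed) & 0x7FFFFFFF,
         zlib.crc32(image_id.encode()), zlib.crc32(label.encode())])


def extract_record(image: np.ndarray, rois: dict, image_id: str,
                   config: PipelineConfig) -> dict:
    """Raw means, calibrated colors and contrasts for one photograph."""
    if "gray_standard" not in rois:
        raise CamoquantError(f"{image_id}: no gray_standard ROI")
    n = config.points_per_region
    raw = {}
    for label, roi in rois.items():
        raw[label] = sampling.region_mean_color(
            image, roi, n, _roi_seed(config.seed, image_id, label))
    if "background_1" in rois and "background_2" in rois:
        raw["background"] = (raw["background_1"] + raw["background_2"]) / 2.0
    rec: dict = {"id": image_id}
    gray_raw = raw["gray_standard"]
    cal = {}
    for label in ("dorsal", "ventral", "ventral_tail", "background"):
        if label not in raw:
            continue
        for i, ch in enumerate("RGB"):
            rec[f"{label}_{ch}_raw"] = raw[label][i]
        c = colorcore.calibrate(raw[label], gray_raw, config.gamma,
                                config.gray_reflectance)
        cal[label] = c
        m = colorcore.color_metrics(c)
        rec.update({f"{label}_{ch}": v for ch, v in zip("RGB", tuple(c)[:3])})
        rec[f"{label}_V"] = c.V
        rec.update({f"{label}_x": m.x, f"{label}_y": m.y,
                    f"{label}_S": m.S, f"{label}_H": m.H})
    if "background" in cal:
        tbl = contrast.region_contrast_table(
            {r: cal.get(r) for r in contrast.BODY_REGIONS}, cal["background"])
        for _, row in tbl.iterrows():
            rec[f"{row['region']}_achromatic"] = row["achromatic"]
            rec[f"{row['region']}_chromatic"] = row["chromatic"]
            rec[f"{row['region']}_abs_achromatic"] = row["abs_achromatic"]
    return rec


def run_pipeline(image_dir, roi_dir, metadata_csv: Optional[str],
                 config: PipelineConfig, out_dir) -> pd.DataFrame:
    """Process every image in ``image_dir``; write records CSV + manifest."""
    image_dir, roi_dir = Path(image_dir), Path(roi_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = None
    if metadata_csv is not None:
        meta = pd.read_csv(metadata_csv, dtype={"id": str}).set_index("id")
    records, manifest_rows = [], []
    images = sorted(image_dir.glob("*.png")) + sorted(image_dir.glob("*.tif*"))
    if not images:
        log.warning("no input images found in %s", image_dir)
    for img_path in images:
        image_id = img_path.stem
        roi_path = roi_dir / f"{image_id}.json"
        status, reason = "processed", ""
        if not roi_path.exists():
            status, reason = "skipped", "no ROI file"
        else:
            try:
                rois = sampling.load_rois(roi_path)
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise CamoquantError(
                    f"malformed ROI JSON: {roi_path}") from exc
            if "gray_standard" not in rois:
                status, reason = "skipped", "missing gray standard"
            else:
                image = np.asarray(Image.open(img_path).convert("RGB"))
                rec = extract_record(image, rois, image_id, config)
                if meta is not None and image_id in meta.index:
                    rec.update(meta.loc[image_id].to_dict())
                records.append(rec)
        if status == "skipped":
            log.warning("%s: %s", image_id, reason)
        manifest_rows.append({"image": image_id, "status": status,
                              "reason": reason})
    df = pd.DataFrame(records)
    df.to_csv(out_dir / "records.csv", index=False)
    manifest = {"version": __version__, "seed": config.seed,
                "config_digest": config.digest(),
                "config": json.loads(config.to_json()),
                "images": manifest_rows}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return df


def validate_inputs(image_dir, roi_dir, metadata_csv=None) -> list:
    """Report every image/ROI/metadata inconsistency without mutating anything."""
    image_dir, roi_dir = Path(image_dir), Path(roi_dir)
    issues = []
    images = {p.stem: p for p in
              list(image_dir.glob("*.png")) + list(image_dir.glob("*.tif*"))}
    for image_id, img_path in sorted(images.items()):
        roi_path = roi_dir / f"{image_id}.json"
        if not roi_path.exists():
            issues.append(f"{image_id}: no ROI file")
            continue
        try:
            rois = sampling.load_rois(roi_path)
        except Exception as exc:
            issues.append(f"{image_id}: unreadable ROI JSON ({exc})")
            continue
        shape = np.asarray(Image.open(img_path)).shape
        if "gray_standard" not in rois:
            issues.append(f"{image_id}: missing gray_standard ROI")
        for label, roi in rois.items():
            if label not in ROI_LABELS:
                issues.append(f"{image_id}: unknown ROI label '{label}'")
            if not roi.within_bounds(shape):
                issues.append(f"{image_id}: ROI '{label}' has out-of-bounds "
                              "vertices")
            elif not roi.is_simple():
                issues.append(f"{image_id}: ROI '{label}' self-intersects")
    for roi_path in sorted(roi_dir.glob("*.json")):
        if roi_path.stem not in images:
            issues.append(f"{roi_path.stem}: ROI file without an image")
    if metadata_csv is not None:
        meta = pd.read_csv(metadata_csv, dtype={"id": str})
        dup = meta["id"][meta["id"].duplicated()]
        for d in dup:
            issues.append(f"{d}: duplicate id in metadata")
        for mid in meta["id"]:
            if mid not in images:
                issues.append(f"{mid}: metadata row without an image")
    return issues


# ---------------------------------------------------------------------------
# Analysis battery
# ---------------------------------------------------------------------------

def add_derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Append color metrics (V, x, y, S, H) and contrasts to a table whose
    ``{region}_{R,G,B}`` columns are already on the calibrated reflectance
    scale (e.g. a synthetic population table)."""
    out = df.copy()
    for reg in ("dorsal", "ventral", "ventral_tail", "background"):
        cols = [f"{reg}_{ch}" for ch in "RGB"]
        if not all(c in out.columns for c in cols):
            continue
        rgb = out[cols].to_numpy(float)
        total = rgb.sum(axis=1)
        x = (rgb[:, 0] - rgb[:, 1]) / total
        y = (rgb[:, 1] - rgb[:, 2]) / total
        s = np.hypot(x, y)
        out[f"{reg}_V"] = total / 3.0
        out[f"{reg}_x"] = x
        out[f"{reg}_y"] = y
        out[f"{reg}_S"] = s
        out[f"{reg}_H"] = np.where(s == 0, np.nan, np.arctan2(y, x))
    return contrast.table_contrasts(out)

def seasonal_contrast_summary(df: pd.DataFrame,
                              column: str = "dorsal_chromatic") -> pd.DataFrame:
    """Per-season mean, SE and count of a contrast column (adults only when
    an age column is present, matching the seasonal analysis design)."""
    d = df
    if "age" in d.columns:
        d = d[d["age"] == "adult"]
    g = d.groupby("season")[column]
    out = pd.DataFrame({"mean": g.mean(),
                        "se": g.std(ddof=1) / np.sqrt(g.count()),
                        "n": g.count()})
    return out.reindex([s for s in ("nb", "bm", "bb") if s in out.index])


def analyze_table(df: pd.DataFrame, config: PipelineConfig) -> dict:
    """Run the full statistical battery on a records table.

    Returns {"tests": {...}, "model_comparison": ModelComparison or None,
    "contrasts": {...}, "seasonal_summary": DataFrame, "regressions": {...}}.
    """
    results: dict = {"tests": {}, "contrasts": {}, "regressions": {}}

    # region comparisons (paired within individuals)
    for kind in ("achromatic", "chromatic"):
        for ra, rb in (("dorsal", "ventral"), ("dorsal", "ventral_tail"),
                       ("ventral", "ventral_tail")):
            ca = df[f"{ra}_{kind}"] if kind == "chromatic" \
                else df[f"{ra}_{kind}"].abs()
            cb = df[f"{rb}_{kind}"] if kind == "chromatic" \
                else df[f"{rb}_{kind}"].abs()
            ok = ca.notna() & cb.notna()
            res = stats.paired_signed_rank(ca[ok], cb[ok])
            results["tests"][f"{kind}:{ra}-vs-{rb}"] = res.as_dict()

    # contrast against the vegetation gradient
    if "vegetation_cover" in df.columns:
        for kind in ("chromatic", "achromatic"):
            col = df[f"dorsal_{kind}"]
            ok = col.notna() & df["vegetation_cover"].notna()
            reg = stats.linear_regression(col[ok], df.loc[ok, "vegetation_cover"])
            results["regressions"][f"dorsal_{kind}~cover"] = dataclasses.asdict(reg)

        # pattern spatial structure
        if "pattern" in df.columns:
            kw = stats.kruskal_wallis(df["vegetation_cover"], df["pattern"])
            results["tests"]["cover~pattern"] = kw.as_dict()
            for pat in sorted(df["pattern"].unique()):
                a = df.loc[df["pattern"] == pat, "vegetation_cover"]
                b = df.loc[df["pattern"] != pat, "vegetation_cover"]
                if len(a) and len(b):
                    results["tests"][f"cover:{pat}-vs-rest"] = \
                        stats.rank_sum_test(a, b).as_dict()

    # AICc candidate ranking for dorsal chromatic contrast
    results["model_comparison"] = None
    needed = {"vegetation_cover", "age", "season", "pattern", "year"}
    if needed <= set(df.columns) and len(df) > 12:
        d = df.dropna(subset=["dorsal_chromatic"]).copy()
        candidates = [
            stats.fit_lmm(d, "dorsal_chromatic", list(terms), "year", label)
            for label, terms in config.candidate_models]
        results["model_comparison"] = stats.rank_models(candidates)

    # signalling: ventral saturation by age and (adults) by sex
    if "age" in df.columns and "ventral_S" in df.columns:
        results["contrasts"]["ventral_S~age"] = stats.pairwise_contrasts(
            df["ventral_S"], df["age"])
        adults = df[df["age"] == "adult"]
        if "sex" in df.columns and adults["sex"].nunique() > 1:
            results["contrasts"]["ventral_S~sex(adults)"] = \
                stats.pairwise_contrasts(adults["ventral_S"], adults["sex"])
        if "season" in df.columns and "dorsal_chromatic" in df.columns:
            results["contrasts"]["dorsal_chromatic~season(adults)"] = \
                stats.pairwise_contrasts(adults["dorsal_chromatic"],
                                         adults["season"])

    # body condition
    if {"mass_g", "svl_mm"} <= set(df.columns):
        adults = df[df["age"] == "adult"] if "age" in df.columns else df
        if len(adults) >= 3:
            smi = stats.scaled_mass_index(adults["mass_g"], adults["svl_mm"])
            results["smi"] = pd.Series(smi, index=adults.index)

    if "season" in df.columns and "dorsal_chromatic" in df.columns:
        results["seasonal_summary"] = seasonal_contrast_summary(df)
    return results


def write_analysis(results: dict, out_dir) -> None:
    """Serialize an analyze_table result bundle to CSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tests = {"tests": results["tests"],
             "regressions": results.get("regressions", {})}
    (out / "tests.json").write_text(json.dumps(tests, indent=1, sort_keys=True))
    mc = results.get("model_comparison")
    if mc is not None:
        mc.table.to_csv(out / "model_comparison.csv", index=False)
    rows = []
    for name, tbl in results.get("contrasts", {}).items():
        t = tbl.copy()
        t.insert(0, "analysis", name)
        rows.append(t)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            out / "contrasts.csv", index=False)
    ss = results.get("seasonal_summary")
    if ss is not None:
        ss.to_csv(out / "seasonal_summary.csv")
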