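# Methods

## Calibration model

Camera JPEG values are not linear in scene radiance. With only a single
in-frame gray standard the full camera response is unidentifiable, so
calibration adopts the standard two-step approximation:

* **Linearization**: `v_lin = v_raw^γ`, γ = 2.2 by default (sRGB-class tone
  curve), configurable per run. One reference patch cannot constrain a
  polynomial response fit; multi-level standards would be needed for that.
* **Equalization**: per-channel scaling `c_out = t · c_lin / g_lin`, where
  `g_lin` is the linearized gray-card observation and `t` its known
  reflectance (0.18). The gray card is an exact fixed point: it always maps
  to `(t, t, t)`.

Calibrated channels are therefore *reflectance-scale* estimates valid under
the illumination of that photograph. The synthetic camera (below) uses the
same functional form, so calibration inverts it exactly up to noise and
8-bit quantization — which is precisely what makes the round trip testable.

Brightness is defined as `V = (R+G+B)/3`. Whether the original extraction
tool reported mean, max or sum of channels is not derivable from a single
scalar; the mean is used because it is consistent with the achromatic
contrast index, which works with channel sums.

Hue uses the full-quadrant angle `atan2(y, x)` in radians, range (−π, π].
The one-argument arctangent form collapses quadrants, and gray-green animal
colors (negative `x`) occur in practice, so the two-argument form is
required for consistency. Achromatic colors have no hue: the scalar path
raises an error and the vectorised table path stores NaN, so achromatic
rows can never silently contribute a spurious 0 rad to circular summaries.

## Sampling conventions

Region colors are means over `points_per_region` (default 400) random
points. Conventions are fixed bit-exactly for reproducibility:

* coordinates are 0-based `(col, row)`; pixel centers at integer positions;
* polygon containment by the even-odd (ray-crossing) rule on pixel centers;
* sampling is uniform *with replacement* over the interior pixel set (the
  minimal reading of "random points", and it makes the sampler's variance
  exactly `σ²_pixels / n`);
* the two background polygons are averaged *unweighted* (a plain mean of
  the two region means), each drawn from its own child seed stream.

`full_region_mean` (mean over every interior pixel) is the oracle the
sampler is tested against: the 400-point mean must sit inside the
`3σ/√400` CLT band in ≥99% of seeded draws.

## Contrast indices

* Achromatic: `(ΣRGB_s − ΣRGB_b) / (ΣRGB_s + ΣRGB_b)`, range [−1, 1]. The
  sign is retained because it carries the darker/lighter direction; the
  absolute value is provided alongside for "how well matched" analyses.
* Chromatic: Euclidean distance between RGB proportion triples
  (`R/(R+G+B)`, …), range [0, √2]. Brightness-invariant, symmetric, and a
  true metric on the simplex (the triangle inequality is property-tested).

Missing body regions yield explicitly flagged NaN rows, never silent drops.

## Pattern classification

The four dorsal types form a 2×2 rule over two features computed from
binary rasters with the body axis horizontal:

* `speckle_score` = speckle pixels / body pixels. "Dense" means
  `score ≥ dense_threshold`; the default 0.10 operationalizes a by-eye
  judgment and is configurable — it is an operational choice, not a
  recovered field parameter. Test fixtures keep ≥10% clear of it.
* `midline_coverage` = fraction of body-axis columns containing a midline
  pixel. "More than 50%" is read strictly: exactly 0.5 is not lined.

Extracting the rasters from raw photographs (segmentation) is out of scope;
the generator emits them directly, and real use accepts externally produced
masks.

## Vegetation cover score

The habitat photo is partitioned into 2×2 quadrants; each section scores
the percentage of the *whole image* that is vegetated within it, rounded
half-up to the nearest 5 and capped at 25; the four scores sum to 0–100.
Any nonzero vegetation scores at least 5 (the smallest nonzero step of the
scale, mirroring a by-eye protocol's minimum), so a sub-2.5% sliver is
deliberately inflated to 5; the ±10 rounding bound is stated for masks
whose nonzero sections carry at least the 2.5% grain. Grid-aligned masks
are recovered exactly.

## Statistics

* **Scaled mass index**: `SMI_i = m_i (L0 / L_i)^{b_SMA}` with
  `b_SMA = b_OLS / r` from the ln mass ~ ln SVL regression and `L0` the
  arithmetic mean SVL by default. If every length already equals `L0` the
  exponent is moot and masses are returned unchanged; estimating the
  allometry itself from zero-variance lengths is an error.
* **AICc**: `−2ℓ + 2k + 2k(k+1)/(n−k−1)`, defined only for `n > k+1`.
  `k` counts fixed coefficients plus two variance components (residual and
  random-intercept variance); AICc comparability depends on this convention
  so it is fixed, not configurable.
* **Model ranking** is exhaustive over a declared candidate list (not
  greedy stepwise): reproducible and order-independent. Ties break by
  fewer parameters, then label.
* **Mixed models**: random intercept per survey year only, fitted by
  maximum likelihood (not REML, so log-likelihoods are AICc-comparable
  across fixed-effect structures). Several optimizers are tried and the
  best finite-likelihood fit kept; when the between-group variance
  collapses, the zero-variance boundary solution equals OLS and is reported
  as such (`group_var = 0`). Singular designs raise an error naming the
  collinear columns.
* **Rank tests** fix their exact-vs-approximate thresholds: signed-rank
  uses the exact null for ≤25 nonzero untied differences, rank-sum for
  combined n ≤ 20 without ties; otherwise normal approximations with tie
  correction. Each result records which route was taken. Kruskal–Wallis
  with all-identical values returns H = 0 (p = 1) by convention rather
  than 0/0.
* **Pairwise contrasts**: single-step Tukey HSD (studentized range on the
  pooled-error model) by default, Holm step-down on pooled-variance t tests
  as the fallback; the method used is recorded in the output. Groups with
  fewer than two observations are flagged and skipped, not dropped
  silently.

The four-level pattern response is summarized by Kruskal–Wallis and
rank-sum spatial-structure tests rather than a multinomial mixed model,
which is out of scope.

## Synthetic data: what it emulates, and what it does not

The generator defines the study conditions for every test.

**Scenes.** 100×150 px frames: a 100×100 habitat region (sand plus blocky
vegetation aligned to the 5% scoring grid), uniform body-region patches,
and an 18% gray card, all pushed through the camera model
*gain → gamma-compression → additive Gaussian noise → 8-bit quantization* —
the simplest model the calibration can exactly invert. All randomness flows
from one top-level seed through named substreams.

**Populations** (defaults, one row per photographed individual, n = 352
across three survey years 19/271/62, seasons nb/bm/bb at 40/30/30%):

| quantity | default | rationale |
|---|---|---|
| background V vs cover | 0.45 − 0.0030·cover | steep decline: vegetated ground is much darker than pale sand |
| dorsal V vs cover | 0.42 − 0.0012·cover | weak tracking: animals darker than background on sand, lighter in dense cover |
| chromatic offset | 0.08 + 0.0008·cover (sd 0.02) | background chromaticity drifts green-ward from the animal's point; expected dorsal chromatic contrast is exactly linear in cover with a known slope |
| ventral saturation | 0.10 + 0.05·adult + 0.03·(adult male) | age/sex signaling structure on the hidden surface |
| dorsal hue | seasonal offsets (+0.25/+0.05/−0.20 rad) and cover slopes (0.004/0.002/0 rad per %) | seasonal green–brown shifts, cover-tracking outside the birthing season |
| pattern mix | (21, 67, 32, 232)/352 base, complexity-weighted along cover | observed population frequencies; complexity increases with cover |
| allometry | mass = 2.1·10⁻⁵ · SVL³ · e^ε, σ_ε = 0.08 | cube-law scaling giving ≈4.5 g at 60 mm SVL |

Effect magnitudes are the package's own field-realistic choices: published
analyses of such systems typically report direction, r² and significance
rather than raw slopes, so the defaults are set once to reproduce the
reported directions at a comparable r² scale and are not tuned thereafter.

The generator deliberately anchors each individual's background
chromaticity at that individual's dorsal point plus a cover-linear offset.
This makes the generating contrast slope exact (and recoverable within
±2 SE), at the cost of a mild physical idealisation — real backgrounds do
not covary with their occupant. Other idealisations: uniform body patches
(no within-region texture or gradients), no shadows or specular
highlights, no segmentation error in ROIs, Gaussian noise, a single gamma
shared by camera and calibration, and independence of individuals. Passing
tests therefore validate the *computational chain* — calibration inverts
the camera model, the sampler converges, the classifiers recover ground
truth, the tests hold their size — not robustness to field artifacts such
as illumination gradients, mis-drawn ROIs or non-gamma camera responses.

## Problem sizes and numerical choices

Default verification scales, chosen to exercise each guarantee at full
protocol size: 100 scenes for the calibration round trip (1% relative
tolerance), 1,000 seeded draws for the sampler band (≥99% within 3σ),
200 maps for classifier recovery (100% required, parameters ≥10% from both
thresholds), 21 grid + 200 arbitrary masks for cover scoring (±5 / ±10),
100 populations for slope-recovery coverage (≥95% within ±2 SE — the
nominal coverage of a 2-SE band is ≈95.4%, so this bound sits essentially
at its expected value), and 2,000 null replicates for test size (≤6% at
α = 5%). Exact formula checks use 1e−12 relative tolerance; scale-invariance
properties 1e−12; mixed-model boundary agreement with OLS 1e−6.

Rounding in the cover score is half-up (`floor(pct/5 + 0.5)·5`), fixed to
avoid banker's-rounding surprises at section boundaries. ROI rectangles
place edges at half-integer coordinates so no pixel center ever lies on a
polygon boundary.

## Known limitations

* Calibrated RGB is camera-referred reflectance, not a perceptual space: no
  receptor-noise modelling, no UV, no viewer-specific discriminability.
* The single-standard calibration cannot correct channel crosstalk or
  spatially varying illumination within a frame.
* The dense-speckling threshold is an operationalization of a qualitative
  field judgment; classifications near 0.10 speckle fraction are
  convention, not biology.
* The 2×2 section partition of the cover score is one reading of a
  sectioned by-eye protocol (four sections capped at 25% each); finer
  grids would change the rounding bound.
* Mixed models support a single random intercept; crossed or nested random
  effects and random slopes are out of scope.
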