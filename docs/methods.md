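# Methods

## Data model

A `Raster` is a 2D grid with an affine pixel→map transform, a CRS identifier
and a nodata sentinel (−9999 for continuous rasters, 255 for categorical
ones). All rasters combined in one operation must share shape, transform and
CRS; areas are `count × |det(transform)| / 10⁶` km², so any area-returning
operation requires a projected (metric) CRS and refuses geographic ones.
Pixel-in-zone assignment uses the pixel **center point** against the zone
polygon, first zone wins; this rule is deterministic and makes zonal areas
exactly additive. Rasters are stored as single- or multi-band TIFF with the
georeferencing (transform, CRS id, nodata, band dates) carried as a JSON
document in the image description tag; round-trips are bit-exact for the
declared dtype (float32 / uint8).

## SAR preprocessing

Backscatter is analysed in decibels (`10·log10` of linear power; nonpositive
power becomes nodata). Each scene is despeckled with a nodata-aware 3×3
focal median before compositing (configurable window, or off) — the median
was chosen over a boxcar because it preserves flood edges and is
deterministic; whether despeckling precedes or follows compositing was an
open design point, and per-scene filtering was chosen so a single outlier
acquisition cannot corrupt the temporal minimum. Composites skip missing
observations instead of invalidating the pixel (sparse coverage is the norm
for flood-period stacks); a pixel valid in zero scenes is nodata.

## Change detection and classification

`D = min(F) − min(R)` (dB) and
`NDFI = (mean(R) − min(R∪F)) / (mean(R) + min(R∪F))`, with `min(R∪F)` the
per-pixel minimum over the concatenation of both stacks (not an arithmetic
sum) and near-zero denominators mapped to nodata. Both indices are computed
in the dB domain; the negative sign of operationally calibrated NDFI
thresholds is consistent with that choice.

The filter cascade produces boolean eligibility masks that are intersected
(order-independent):

* terrain: Horn 3×3 slope ≤ 5°, inclusive, with a 1e-9° guard against
  floating-point rounding at the boundary;
* background: `|D| > 1e-6` dB, defined on the CDAT difference image only
  (applying it to NDFI is rejected as a contract violation);
* seasonal: `min(F)` strictly below the land–water cutoff, default −19 dB;
  pixels that darken but stay above the cutoff are treated as seasonal
  land-cover change, not flooding. The filter is applied to both algorithms'
  candidates.

Thresholding offers three routes:

* **auto** — `T = mean(I) − K_c·std(I)` with `K_c = 1.5` and population
  standard deviation (configurable to sample), computed over pixels that
  survive the three filters so excluded land does not bias `T`;
* **calibrated** (pipeline default) — repeated re-partition of the labeled
  samples into train/validation thirds (default 5 repeats), exhaustive
  search over the unique train index values (every classification reachable
  with the strict `index < T` rule, plus a sentinel above the maximum),
  best training-OA candidate scored on the validation split, best validator
  across repeats wins. The returned threshold is centered in the decision
  gap between the winning candidate and the nearest train value below it,
  which leaves the sample classification unchanged and is more robust on
  unseen pixels. The calibrated route is the default because operational
  thresholds for this method family are sample-derived rather than taken
  from the closed form;
* **fixed** — user-supplied values.

Decisions at the threshold are strictly `index < T`; a pixel exactly at `T`
is non-flooded. The synergy map is the pixelwise AND of the CDAT and NDFI
binary maps (nodata if either side is nodata).

## Severity, frequency, newly-added area

Intensity is the per-pixel sum of the per-stage binary maps (0–3 for the
three-stage design; more stages trigger a warning). Frequency is the same
sum across annual maps (0–6). "Maximum ever-flooded" is the pixelwise union
of prior-year maps — the only reading consistent with "ever" — and the
newly-added share is `100 × area(current ∧ ¬union) / area(union)`, rounded
half-away-from-zero to an integer percent, matching how such shares are
printed. Per-stage maps come from independent runs of the mapper for each
stage window against the single reference period, with thresholds resolved
once on the full flood period and reused across stages and years.

## Validation

The confusion matrix takes flooded as the positive class. Metrics are OA,
UA (precision) and PA (recall) per class, in percent, and the flooded-class
F1 as the standard harmonic mean of precision and recall; zero denominators
yield NaN and are flagged rather than silently zeroed. The optical
cross-map uses NDVI, EVI and LSWI from 0–10000-scaled reflectance (the EVI
canopy/aerosol constant is +10000 on that scale; a 0–1 pipeline would use
+1) and the rule `flooded = (LSWI > EVI) AND (NDVI > 0.1)` with strict
inequalities. Zone-level agreement between two maps is the R² of an
ordinary least-squares fit of one zone-area vector on the other;
zero-variance inputs make R² undefined (NaN with a warning).

## Cropland damage

NDVI and EVI differences are post-window minus pre-window means; DVDI is the
change in `mVCI = (NDVI − NDVI_med) / (NDVI_max − NDVI_med)`, with the
median and maximum taken **per pixel** over the historical series (the
standard construction for condition indices of this family). Pixels whose
historical maximum does not exceed the median are nodata.

Each change raster is reclassified over flooded-cropland pixels only (so
statistics are not diluted by unaffected land) into 4 classes by the
geometrical-interval method: class breaks between the minimum and maximum
whose successive widths form a geometric progression with common ratio `r`.
Because the originating GIS implementation of this classifier is
undocumented, `r` is selected by a dense deterministic grid search in
`log r` over [1/8, 8] minimising the variance of per-class pixel counts
(ties toward `r = 1`); the tested contract is the definitional
constant-ratio property of the breaks. Class order puts the most-negative
interval (strongest decline) in class 3 and the least in class 0; a constant
raster degenerates to class 0 with a warning, and inputs with fewer distinct
values than classes are still classified by the same breaks (the noise-free
synthetic case produces exactly three distinct decline values).

Severity degree is `(NDVI_cls + EVI_cls + DVDI_cls + intensity) / 4`,
defined only where intensity ≥ 1 on cropland, hence in (0, 3]; classes are
slight (0,1], moderate (1,2], severe (2,3] (half-open on the left, closed on
the right, so a degree of exactly 2 is moderate). Class shares are integer
percents of the summed three-class area.

## Synthetic scenes

The generator emulates the statistical structure of the imagery, not its
physics:

* **Backscatter**: land −8 dB, open water −20 dB, plus a static per-pixel
  spatial texture (σ = 1 dB) that is constant through time (so it cancels in
  the difference image, as stable terrain should).
* **Speckle**: multiplicative Gamma noise in **linear power** with shape =
  equivalent number of looks (L = 10 by default; `looks=None` disables it) —
  the standard multi-look speckle model; additive dB noise would misstate
  the heavy lower tail that drives the temporal minimum. The model is
  unbiased in linear power (verified to <2% at 10⁴ draws).
* **Geometry**: a local metric CRS at 10 m pixels on a 160×160 grid, so
  areas are exact and no reprojection is needed. The default layout has a
  large permanent lake (≈30% of the scene — in lake-plain flood settings
  open water far exceeds any single flood, which also keeps the `mean −
  K_c·std` threshold meaningful on the filtered candidate population), a
  nested three-stage flood belt south of it (≈8% at stage 1) giving
  intensities 1–3, five prior-year flood extents that partly overlap the
  current one, an eastern hill block with a 10° ramp for the terrain filter,
  and two seasonal-change confounder patches (≈0.5% of the scene) that drop
  to −21 dB in the flood period only — deliberately below the −19 dB cutoff
  to exercise the cascade's known failure mode. Confounders are labeled
  non-flood in the truth.
* **Cropland**: a block over the southern plain with rice and other crops
  interleaved in column bands at a 90/10 ratio.
* **Vegetation indices**: baselines NDVI 0.70 / EVI 0.50; post-flood values
  on flooded pixels are depressed by intensity-dependent amounts
  (NDVI −0.15/−0.30/−0.45, EVI −0.10/−0.20/−0.30) plus N(0, 0.02) noise. The
  historical NDVI series (20 years) is stationary around the baseline with a
  small deterministic interannual swing (amplitude 0.05) so the mVCI
  denominator is well defined even at zero noise.
* **Optical bands**: class-typical 0–10000 reflectances chosen so the
  optical rule recovers the flood truth (flooded pixels: moderate NDVI, LSWI
  above EVI; permanent water: negative NDVI) with N(0, 50) noise.
* **Sampling**: stratified flooded/non-flooded points (default 3000 at 43%
  flooded = 1290/1710), drawn without replacement after eroding each class
  mask by one pixel to avoid mixed edge pixels; one third train, two thirds
  validation. Everything is deterministic given the seed.

What the synthetic scene does **not** emulate — and hence what passing tests
do not establish about real data: orbit geometry, incidence-angle and
polarization effects, layover/shadow, urban double-bounce, partially
submerged vegetation, wind roughening of water, spatially correlated
speckle, cloud contamination of the optical bands, and mixed pixels beyond
the one-pixel class boundaries. Detection on these scenes is substantially
easier than on real imagery; the synthetic results validate the
implementation, not the method's field accuracy.

## Problem sizes and determinism

Default runs use a 160×160 scene, 4 reference + 3 scenes per flood stage,
3000 samples and 5 calibration repeats — small enough that a full
end-to-end run completes in a couple of seconds while every class of pixel
(land, lake, three intensities, hills, confounders, both crop types) is
populated by hundreds of pixels. All randomness flows from a single integer
seed through separate sub-seeds for scene generation, sampling and
calibration; re-running with the same configuration reproduces outputs
byte-for-byte.

## Known limitations

* The decision tree is pixel-based; no object-based or region-growing
  refinement, flood-depth estimation, or urban handling.
* Reprojection between CRSs is out of scope; all inputs must be
  co-registered on one metric grid.
* The adaptive (`mean − K_c·std`) threshold assumes flood pixels are a
  minority tail of the filtered candidate histogram; on scenes where the
  flood dominates the candidates it collapses, which is why the calibrated
  route is the default.
* The geometric-interval ratio search is a pragmatic reconstruction of an
  undocumented proprietary classifier; only the constant-ratio property of
  its breaks is contractual.
* Printed-percent reporting uses round-half-away-from-zero; shares may not
  sum to exactly 100.
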