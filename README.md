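# floodscope

Synergic SAR change-detection flood mapping with flood-severity and
cropland-damage assessment.

## The problem

Floods in large river–lake plains must be mapped quickly and over wide areas.
Optical imagery fails under the storm clouds that accompany floods, so
C-band SAR backscatter (σ⁰, in dB) is the workhorse: open water is a smooth
specular surface and returns very little energy, appearing dark. Single-image
water mapping, however, confuses floods with permanent water bodies.
`floodscope` implements a change-detection framework that contrasts a
flood-period image stack **F** against a relatively dry reference stack
**R**, plus the downstream analyses a disaster-assessment workflow needs:
multi-stage flood intensity, multi-year inundation frequency, newly-added
flooded area, accuracy assessment against labeled samples and an optical
cross-map, and a vegetation-index damage score over flooded cropland.

It is aimed at remote-sensing scientists who want a tested, reusable,
fully synthetic-testable implementation of this pipeline: every stage can be
exercised on generated scenes with known ground truth, no downloads needed.

## The method

Two change indices are computed per pixel from dB composites:

* **CDAT difference** (change detection and thresholding):
  `D = min(F) − min(R)`; new inundation pulls the flood-period minimum far
  below the reference minimum, so strongly negative `D` marks floods.
* **NDFI** (normalized difference flood index):
  `NDFI = (mean(R) − min(R∪F)) / (mean(R) + min(R∪F))`, where `min(R∪F)` is
  the minimum over both stacks; on negative-dB imagery flooded pixels give
  markedly negative values.

A decision tree removes non-flood pixels before thresholding:

1. **terrain filter** — slope ≤ 5° (Horn 3×3 slope on the DEM);
2. **background filter** — `|D| > ε`, dropping unchanged pixels, including
   permanent water (dark in both periods);
3. **seasonal filter** — flood candidates must have `min(F)` below a
   land–water cutoff (−19 dB), separating floods from seasonal land-cover
   darkening.

The classification threshold is either adaptive, `T = mean(I) − K_c·std(I)`
with `K_c = 1.5` over the filtered index values, or calibrated by repeated
train/validation re-partition of labeled samples (the default, and the route
that mirrors operational practice). Flooded = index strictly below `T`,
intersected with the filters. The **synergy (consistency) map** is the
pixelwise AND of the CDAT and NDFI maps, trading a little detection for much
lower commission error.

Downstream: flood **intensity** = count of intra-season stage maps flagging a
pixel (1–3); **frequency** = count of flooded years (0–6); **newly-added
area** = current flooding never seen in prior years, reported against the
pixelwise union of the prior extents. Over flooded cropland, NDVI/EVI
post-minus-pre differences and the DVDI (change of a modified vegetation
condition index anchored at the historical NDVI median/maximum) are each
reclassified into 4 ordinal classes with the geometrical-interval method, and
the composite **severity degree** `= (NDVI_cls + EVI_cls + DVDI_cls +
intensity)/4` is classed slight (0,1], moderate (1,2], severe (2,3].

## Worked example

```python
from floodscope import PipelineConfig, run_end_to_end

result = run_end_to_end(PipelineConfig(seed=1), outdir="scratch/demo")
print("OA = %.2f%%, F1 = %.4f" % (result.metrics["OA"], result.metrics["F1"]))
print("stage areas (km²):", result.manifest["stage_area_km2"])
print("newly added: %.4f km² = %d%%" % (result.newly_added_km2, result.newly_added_pct))
print("damage shares:", result.damage_stats)
```

prints (seed 1):

```
OA = 99.80%, F1 = 0.9977
stage areas (km²): [0.2175, 0.1269, 0.0577]
newly added: 0.0702 km² = 25%
damage shares: {'slight_km2': 0.0454, 'moderate_km2': 0.0447, 'severe_km2': 0.0311,
                'slight_share_pct': 37, 'moderate_share_pct': 37, 'severe_share_pct': 26}
```

The run simulates a 160×160 scene at 10 m (a large permanent lake, a nested
three-stage flood belt, hills, seasonal-change confounders, rice-dominated
cropland), maps each stage with both algorithms under sample-calibrated
thresholds (here CDAT `T ≈ −6.3` dB, NDFI `T ≈ −0.26`), and validates the
synergy map on 2000 held-out samples: overall accuracy 99.8% with zero
omission of flooded samples. The stage areas fall as the nested flood
recedes; a quarter of the 2020 extent was never flooded in the five prior
years; and flooded-cropland damage splits into slight/moderate/severe as
shown. The county-style cross-map against the optical flood rule
(`LSWI > EVI` and `NDVI > 0.1`) gives R² ≈ 0.995 over 16 zones.

The same pipeline is exposed as a CLI (`floodscope simulate | mapflood |
severity | frequency | optical-flood | validate | damage | run-all`); rasters
travel as TIFF with JSON georeferencing metadata, zones as GeoJSON, tables
as CSV.

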