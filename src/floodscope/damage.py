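"""Cropland damage scoring from vegetation-index change and flood intensity.

On flooded cropland, three change signals are computed — the NDVI and EVI
differences between post- and pre-flood windows, and the DVDI (change in a
modified vegetation condition index anchored at the historical NDVI median
and maximum):

    mVCI  = (NDVI − NDVI_med) / (NDVI_max − NDVI_med)
    DVDI  = mVCI_after − mVCI_before

Each signal is reclassified into 4 ordinal classes (0 = no damage, 3 =
strongest decline) with the geometrical-interval method — class breaks whose
successive widths form a geometric progression, suited to skewed continuous
data. The composite severity degree is the quarter-weighted sum

    severity = (NDVI_class + EVI_class + DVDI_class + intensity) / 4

over pixels that are both flooded (intensity ≥ 1) and cropland, classed as
slight (0,1], moderate (1,2], severe (2,3].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster, ZoneSet, NODATA_FLOAT, NODATA_INT, zone_assignment
from .severity import round_half_away

__all__ = [
    "flooded_cropland",
    "vi_difference",
    "mvci",
    "dvdi",
    "geometric_interval_breaks",
    "geometric_interval_reclass",
    "severity_degree",
    "damage_report",
    "DamageMap",
]

CROP_NONE, CROP_RICE, CROP_OTHER = 0, 1, 2
_DAMAGE_CLASS_NAMES = {1: "slight", 2: "moderate", 3: "severe"}


@dataclass
class DamageMap:
    """Continuous severity degree plus its slight/moderate/severe classes."""

    degree: Raster  # continuous, (0, 3] on flooded cropland, nodata elsewhere
    classes: Raster  # 0 none / 1 slight / 2 moderate / 3 severe


def flooded_cropland(flood: Raster, crops: Raster) -> tuple[Raster, dict]:
    """Flooded-cropland mask and area accounting by crop type.

    Returns the mask raster (1 = flooded cropland) and a dict with km² of
    flooded cropland per crop type, the total flooded area, the cropland
    share of the flooded area (integer percent) and the rice share of the
    flooded cropland (integer percent).
    """
    flood.require_same_geometry(crops, "flood/cropland rasters")
    valid = flood.valid_mask() & crops.valid_mask()
    fl = (flood.values == 1) & valid
    mask = fl & (crops.values > 0)
    px = flood.transform.pixel_area / 1e6
    rice = int(np.count_nonzero(mask & (crops.values == CROP_RICE))) * px
    other = int(np.count_nonzero(mask & (crops.values == CROP_OTHER))) * px
    crop_total = rice + other
    flood_total = int(np.count_nonzero(fl)) * px
    stats = {
        "flooded_km2": flood_total,
        "flooded_cropland_km2": crop_total,
        "rice_km2": rice,
        "other_km2": other,
        "cropland_share_pct": round_half_away(100.0 * crop_total / flood_total)
        if flood_total > 0
        else 0,
        "rice_share_pct": round_half_away(100.0 * rice / crop_total) if crop_total > 0 else 0,
    }
    mask_r = Raster(
        np.where(valid, mask.astype(np.uint8), np.uint8(NODATA_INT)),
        flood.transform,
        flood.crs_id,
        NODATA_INT,
    )
    return mask_r, stats


def vi_difference(after_mean: Raster, before_mean: Raster) -> Raster:
    """Post-minus-pre vegetation-index change (negative = decline)."""
    after_mean.require_same_geometry(before_mean, "VI windows")
    ok = after_mean.valid_mask() & before_mean.valid_mask()
    out = np.full(after_mean.shape, NODATA_FLOAT, dtype=float)
    out[ok] = after_mean.values[ok] - before_mean.values[ok]
    return after_mean.like(out, NODATA_FLOAT)


def mvci(ndvi_mean: Raster, ndvi_med: Raster, ndvi_max: Raster) -> Raster:
    """Modified vegetation condition index, per pixel.

    (NDVI − NDVI_med)/(NDVI_max − NDVI_med); pixels where the historical
    max does not exceed the median are nodata.
    """
    ndvi_mean.require_same_geometry(ndvi_med, "NDVI rasters")
    ndvi_mean.require_same_geometry(ndvi_max, "NDVI rasters")
    ok = ndvi_mean.valid_mask() & ndvi_med.valid_mask() & ndvi_max.valid_mask()
    den = ndvi_max.values - ndvi_med.values
    ok &= den > 0
    out = np.full(ndvi_mean.shape, NODATA_FLOAT, dtype=float)
    out[ok] = (ndvi_mean.values[ok] - ndvi_med.values[ok]) / den[ok]
    return ndvi_mean.like(out, NODATA_FLOAT)


def dvdi(mvci_after: Raster, mvci_before: Raster) -> Raster:
    """Disaster vegetation damage index: post-minus-pre change in mVCI."""
    return vi_difference(mvci_after, mvci_before)


def historical_med_max(history: list[Raster]) -> tuple[Raster, Raster]:
    """Per-pixel median and maximum of a historical NDVI series."""
    if not history:
        raise ValueError("empty historical series")
    for r in history[1:]:
        history[0].require_same_geometry(r, "historical series")
    cube = np.stack(
        [np.where(r.valid_mask(), r.values.astype(float), np.nan) for r in history]
    )
    with np.errstate(all="ignore"):
        med = np.nanmedian(cube, axis=0)
        mx = np.nanmax(cube, axis=0)
    r0 = history[0]
    return (
        r0.like(np.where(np.isnan(med), NODATA_FLOAT, med), NODATA_FLOAT),
        r0.like(np.where(np.isnan(mx), NODATA_FLOAT, mx), NODATA_FLOAT),
    )


def geometric_interval_breaks(
    vmin: float, vmax: float, n_classes: int, r: float
) -> np.ndarray:
    """Breaks between vmin and vmax with widths w, w·r, w·r², ..."""
    if r == 1.0:
        widths = np.full(n_classes, (vmax - vmin) / n_classes)
    else:
        w0 = (vmax - vmin) * (r - 1.0) / (r**n_classes - 1.0)
        widths = w0 * r ** np.arange(n_classes)
    return vmin + np.concatenate([[0.0], np.cumsum(widths)])


def geometric_interval_reclass(
    raster: Raster,
    n_classes: int = 4,
    r_bounds: tuple[float, float] = (1.0 / 8.0, 8.0),
    n_grid: int = 1537,
) -> tuple[Raster, np.ndarray, float]:
    """Reclassify a continuous raster into ordinal classes by geometric intervals.

    The common ratio r of the break widths is selected over ``r_bounds`` by a
    dense grid search in log(r) minimising the variance of per-class pixel
    counts (ties broken toward r = 1). Classes are ordered so that class
    ``n_classes − 1`` is the most-negative interval (largest decline) and
    class 0 the least.  Returns (class raster, breaks, selected r).
    """
    valid = raster.valid_mask()
    vals = raster.values[valid].astype(float)
    out = np.full(raster.shape, NODATA_INT, dtype=np.uint8)
    if vals.size == 0:
        raise ValueError("no valid pixels to classify")
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmin == vmax:
        warnings.warn("constant raster; all pixels assigned class 0", stacklevel=2)
        out[valid] = 0
        return Raster(out, raster.transform, raster.crs_id, NODATA_INT), np.array(
            [vmin, vmax]
        ), 1.0

    log_r = np.linspace(np.log(r_bounds[0]), np.log(r_bounds[1]), n_grid)
    rs = np.exp(log_r)
    best_r, best_var = 1.0, np.inf
    for r in rs:
        breaks = geometric_interval_breaks(vmin, vmax, n_classes, r)
        counts = np.histogram(vals, bins=breaks)[0]
        var = float(np.var(counts))
        if var < best_var - 1e-12 or (
            abs(var - best_var) <= 1e-12 and abs(np.log(r)) < abs(np.log(best_r))
        ):
            best_var, best_r = var, float(r)
    breaks = geometric_interval_breaks(vmin, vmax, n_classes, best_r)
    # interval index 0 = lowest (most negative) -> damage class n_classes-1
    idx = np.clip(np.searchsorted(breaks, vals, side="right") - 1, 0, n_classes - 1)
    out[valid] = (n_classes - 1 - idx).astype(np.uint8)
    return Raster(out, raster.transform, raster.crs_id, NODATA_INT), breaks, best_r


def severity_degree(
    ndvi_cls: Raster, evi_cls: Raster, dvdi_cls: Raster, intensity: Raster,
    cropland_mask: np.ndarray | None = None,
) -> DamageMap:
    """Composite damage degree = (NDVI_cls + EVI_cls + DVDI_cls + intensity)/4.

    Evaluated only where intensity ≥ 1 (flooded) and, if given, on the
    cropland mask; elsewhere nodata. Classes: slight (0,1], moderate (1,2],
    severe (2,3].
    """
    for r in (evi_cls, dvdi_cls, intensity):
        ndvi_cls.require_same_geometry(r, "severity inputs")
    ok = (
        ndvi_cls.valid_mask()
        & evi_cls.valid_mask()
        & dvdi_cls.valid_mask()
        & intensity.valid_mask()
        & (intensity.values >= 1)
    )
    if cropland_mask is not None:
        ok &= cropland_mask.astype(bool)
    deg = np.full(ndvi_cls.shape, NODATA_FLOAT, dtype=float)
    deg[ok] = (
        ndvi_cls.values[ok].astype(float)
        + evi_cls.values[ok]
        + dvdi_cls.values[ok]
        + intensity.values[ok]
    ) / 4.0
    classes = np.full(ndvi_cls.shape, NODATA_INT, dtype=np.uint8)
    classes[ok] = np.clip(np.ceil(deg[ok] - 1e-12), 1, 3).astype(np.uint8)
    return DamageMap(
        degree=Raster(deg, ndvi_cls.transform, ndvi_cls.crs_id, NODATA_FLOAT),
        classes=Raster(classes, ndvi_cls.transform, ndvi_cls.crs_id, NODATA_INT),
    )


def damage_report(
    damage: DamageMap, crops: Raster, zones: ZoneSet
) -> tuple[pd.DataFrame, dict]:
    """Area per damage class × crop type × zone, plus class shares.

    Shares are integer percents of the summed slight+moderate+severe area.
    """
    cls = damage.classes
    cls.require_same_geometry(crops, "damage/cropland rasters")
    assign = zone_assignment(cls, zones)
    px = cls.transform.pixel_area / 1e6
    valid = cls.valid_mask()
    rows = []
    for zi, (zid, name) in enumerate(zip(zones.zone_ids, zones.names)):
        in_zone = (assign == zi) & valid
        for k, kname in _DAMAGE_CLASS_NAMES.items():
            for crop, cname in ((CROP_RICE, "rice"), (CROP_OTHER, "other")):
                n = np.count_nonzero(in_zone & (cls.values == k) & (crops.values == crop))
                rows.append(
                    {
                        "zone_id": zid,
                        "name": name,
                        "damage_class": kname,
                        "crop": cname,
                        "area_km2": int(n) * px,
                    }
                )
    table = pd.DataFrame(rows)
    class_km2 = {
        kname: int(np.count_nonzero(valid & (cls.values == k))) * px
        for k, kname in _DAMAGE_CLASS_NAMES.items()
    }
    total = sum(class_km2.values())
    shares = {
        f"{kname}_share_pct": round_half_away(100.0 * a / total) if total > 0 else 0
        for kname, a in class_km2.items()
    }
    return table, {**{f"{k}_km2": v for k, v in class_km2.items()}, **shares}
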