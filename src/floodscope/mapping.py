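"""Change-detection flood mapping: CDAT, NDFI, filters, thresholds, synergy.

Two change indices are computed from a reference-period stack R and a
flood-period stack F of dB backscatter:

* CDAT difference  ``D = min(F) − min(R)`` — new open water pulls the
  flood-period minimum far below the reference minimum, so strongly
  negative D marks inundation.
* NDFI  ``(mean(R) − min(R∪F)) / (mean(R) + min(R∪F))`` — contrasts the
  reference-period mean against the minimum over both stacks; on negative-dB
  imagery flooded pixels give markedly negative values.

A decision tree removes non-flood pixels before thresholding: (1) terrain
filter, slope ≤ 5° (Horn 3×3 slope); (2) background filter, |D| > ε (pixels
unchanged between periods, including permanent water, drop out); (3) seasonal
land-cover filter, flood candidates must have min-flood backscatter strictly
below a land–water cutoff (default −19 dB). The adaptive threshold is
``T = mean(I) − Kc·std(I)`` over the pixels surviving the filters (Kc = 1.5
by default); flooded = index strictly below T, intersected with all masks.
The synergy (consistency) map is the pixelwise AND of the CDAT and NDFI maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Raster, Stack, NODATA_FLOAT, NODATA_INT, GeometryError
from .sar import CompositeRaster, temporal_min, temporal_mean

__all__ = [
    "ChangeIndexRaster",
    "ThresholdSpec",
    "cdat_difference",
    "ndfi",
    "adaptive_threshold",
    "terrain_filter",
    "horn_slope",
    "background_filter",
    "seasonal_filter",
    "classify_flood",
    "synergy_map",
    "DEFAULT_KC",
    "DEFAULT_SLOPE_CUTOFF_DEG",
    "DEFAULT_SEASONAL_CUTOFF_DB",
    "BACKGROUND_EPS_DB",
]

DEFAULT_KC = 1.5
DEFAULT_SLOPE_CUTOFF_DEG = 5.0
DEFAULT_SEASONAL_CUTOFF_DB = -19.0
BACKGROUND_EPS_DB = 1e-6


@dataclass
class ChangeIndexRaster:
    """A change index (CDAT difference in dB, or unitless NDFI)."""

    raster: Raster
    algorithm: str  # "CDAT" | "NDFI"

    def __post_init__(self):
        if self.algorithm not in ("CDAT", "NDFI"):
            raise ValueError(f"algorithm must be 'CDAT' or 'NDFI', got {self.algorithm!r}")


@dataclass
class ThresholdSpec:
    """Resolved classification threshold and the parameters that produced it."""

    T: float
    kc: float = DEFAULT_KC
    slope_cutoff_deg: float = DEFAULT_SLOPE_CUTOFF_DEG
    seasonal_cutoff_db: float = DEFAULT_SEASONAL_CUTOFF_DB
    std_kind: str = "population"
    source: str = "auto"  # "auto" | "calibrated" | "fixed"

    def __post_init__(self):
        if not np.isfinite(self.T):
            raise ValueError("threshold T must be finite")
        if self.slope_cutoff_deg < 0:
            raise ValueError("slope cutoff must be >= 0")
        if self.std_kind not in ("population", "sample"):
            raise ValueError("std_kind must be 'population' or 'sample'")

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "kc": self.kc,
            "slope_cutoff_deg": self.slope_cutoff_deg,
            "seasonal_cutoff_db": self.seasonal_cutoff_db,
            "std_kind": self.std_kind,
            "source": self.source,
        }


def cdat_difference(min_flood: CompositeRaster, min_ref: CompositeRaster) -> ChangeIndexRaster:
    """CDAT difference image D = min(F) − min(R), in dB; nodata propagates."""
    if min_flood.statistic != "min" or min_ref.statistic != "min":
        raise ValueError("cdat_difference requires min composites")
    f, r = min_flood.raster, min_ref.raster
    f.require_same_geometry(r, "composites")
    ok = f.valid_mask() & r.valid_mask()
    out = np.full(f.shape, NODATA_FLOAT, dtype=float)
    out[ok] = f.values[ok] - r.values[ok]
    return ChangeIndexRaster(f.like(out, NODATA_FLOAT), "CDAT")


def ndfi(ref_stack: Stack, flood_stack: Stack, eps: float = 1e-9) -> ChangeIndexRaster:
    """NDFI = (mean(R) − min(R∪F)) / (mean(R) + min(R∪F)).

    min(R∪F) is the per-pixel minimum over the concatenation of both stacks.
    Near-zero denominators become nodata.
    """
    if len(ref_stack) == 0 or len(flood_stack) == 0:
        raise ValueError("empty stack")
    mean_r = temporal_mean(ref_stack).raster
    min_rf = temporal_min(ref_stack.concat(flood_stack)).raster
    ok = mean_r.valid_mask() & min_rf.valid_mask()
    num = mean_r.values - min_rf.values
    den = mean_r.values + min_rf.values
    ok &= np.abs(den) > eps
    out = np.full(mean_r.shape, NODATA_FLOAT, dtype=float)
    out[ok] = num[ok] / den[ok]
    return ChangeIndexRaster(mean_r.like(out, NODATA_FLOAT), "NDFI")


def adaptive_threshold(
    index: ChangeIndexRaster,
    kc: float = DEFAULT_KC,
    std_kind: str = "population",
    eligibility: np.ndarray | None = None,
    **spec_kwargs,
) -> ThresholdSpec:
    """Histogram threshold T = mean(I) − Kc·std(I) over eligible valid pixels.

    ``eligibility`` is the boolean intersection of the decision-tree masks
    (terrain, background, seasonal); statistics are computed only over pixels
    that survive them so excluded land does not bias T.
    """
    r = index.raster
    sel = r.valid_mask()
    if eligibility is not None:
        sel &= eligibility.astype(bool)
    vals = r.values[sel]
    if vals.size == 0:
        raise ValueError("no valid pixels for threshold estimation")
    ddof = 0 if std_kind == "population" else 1
    std = float(np.std(vals, ddof=ddof)) if vals.size > ddof else 0.0
    t = float(np.mean(vals)) - kc * std
    return ThresholdSpec(T=t, kc=kc, std_kind=std_kind, source="auto", **spec_kwargs)


def horn_slope(dem: Raster) -> Raster:
    """Terrain slope in degrees via Horn's 3×3 weighted finite differences."""
    t = dem.transform
    z = dem.values.astype(float)
    zp = np.pad(z, 1, mode="edge")
    # 3x3 neighbors: z1 z2 z3 / z4 z5 z6 / z7 z8 z9 (z5 center)
    z1, z2, z3 = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    z4, z6 = zp[1:-1, :-2], zp[1:-1, 2:]
    z7, z8, z9 = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    dx = abs(t.a) if abs(t.a) > 0 else 1.0
    dy = abs(t.e) if abs(t.e) > 0 else 1.0
    dzdx = ((z3 + 2 * z6 + z9) - (z1 + 2 * z4 + z7)) / (8.0 * dx)
    dzdy = ((z7 + 2 * z8 + z9) - (z1 + 2 * z2 + z3)) / (8.0 * dy)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.like(slope, NODATA_FLOAT)


def terrain_filter(dem: Raster, cutoff_deg: float = DEFAULT_SLOPE_CUTOFF_DEG) -> np.ndarray:
    """Eligibility mask: slope ≤ cutoff (inclusive); hills and banks drop out.

    The boundary is inclusive with a 1e-9° guard so a plane at exactly the
    cutoff stays eligible despite floating-point rounding in the gradient.
    """
    return horn_slope(dem).values <= cutoff_deg + 1e-9


def background_filter(d_index: ChangeIndexRaster, eps: float = BACKGROUND_EPS_DB) -> np.ndarray:
    """Eligibility mask on the CDAT difference image: |D| > ε.

    Unchanged pixels (background land and permanent water, which stay dark in
    both periods) have D ≈ 0 and are excluded. Defined on the difference
    image only.
    """
    if d_index.algorithm != "CDAT":
        raise ValueError("background filter is defined on the CDAT difference image")
    r = d_index.raster
    return r.valid_mask() & (np.abs(r.values) > eps)


def seasonal_filter(
    min_flood: CompositeRaster, cutoff_db: float = DEFAULT_SEASONAL_CUTOFF_DB
) -> np.ndarray:
    """Eligibility mask: flood candidates have min-flood backscatter < cutoff.

    Pixels at or above the land–water cutoff that still show a backscatter
    drop are treated as seasonal land-cover change, not flooding.
    """
    r = min_flood.raster
    return r.valid_mask() & (r.values < cutoff_db)


def classify_flood(
    index: ChangeIndexRaster, spec: ThresholdSpec, *masks: np.ndarray
) -> Raster:
    """Binary flood map: flooded where index < T (strict) and all masks hold."""
    r = index.raster
    valid = r.valid_mask()
    flooded = valid & (r.values < spec.T)
    for m in masks:
        if m.shape != r.shape:
            raise GeometryError("eligibility mask shape mismatch")
        flooded &= m.astype(bool)
    out = np.where(valid, flooded.astype(np.uint8), np.uint8(NODATA_INT))
    return Raster(out, r.transform, r.crs_id, NODATA_INT)


def synergy_map(cdat_map: Raster, ndfi_map: Raster) -> Raster:
    """Consistency map: flooded only where both algorithms agree (logical AND)."""
    cdat_map.require_same_geometry(ndfi_map, "flood maps")
    ok = cdat_map.valid_mask() & ndfi_map.valid_mask()
    both = (cdat_map.values == 1) & (ndfi_map.values == 1)
    out = np.where(ok, both.astype(np.uint8), np.uint8(NODATA_INT))
    return Raster(out, cdat_map.transform, cdat_map.crs_id, NODATA_INT)
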