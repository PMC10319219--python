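"""Synthetic SAR/optical flood scenes with known ground truth.

The generator emulates the statistical structure of C-band flood imagery:

* two backscatter classes — land (bright, default −8 dB) and open water
  (dark, default −20 dB) — with a static spatial texture (dB spread σ);
* multiplicative speckle, Gamma-distributed in linear power with shape =
  equivalent number of looks L (``looks=None`` disables it);
* three overlapping (nested) intra-season flood stages giving inundation
  intensities 1–3, plus five prior-year flood extents for frequency and
  newly-added-area accounting;
* a permanent-water body dark in every period, hilly terrain that must be
  removed by the slope filter, and seasonal-change confounder patches whose
  backscatter drops only in the flood period (default −21 dB, below the
  −19 dB land–water cutoff) to exercise the filter cascade's failure modes;
* cropland (rice / other) whose post-flood vegetation indices are depressed
  in proportion to flood intensity, with a stationary historical NDVI series
  for the condition-index baseline.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import box

from .raster import Affine, Raster, Stack, ZoneSet, NODATA_INT
from .validation import LabeledSampleSet, OpticalBands

__all__ = ["SceneConfig", "SceneTruth", "ViSeries", "SceneBundle",
           "generate_scene", "generate_vi_series", "sample_points", "make_zone_grid"]


@dataclass
class SceneConfig:
    """Parameters of the synthetic scene (all overridable)."""

    shape: tuple[int, int] = (160, 160)
    pixel_size: float = 10.0  # m
    crs_id: str = "LOCAL:m"
    mu_land: float = -8.0  # dB
    mu_water: float = -20.0  # dB
    sigma: float = 1.0  # static spatial texture spread, dB
    looks: float | None = 10.0  # equivalent number of looks; None = speckle off
    n_ref_scenes: int = 4
    n_stage_scenes: int = 3
    confounder_db: float = -21.0  # flood-period backscatter of confounder patches
    hill_slope_deg: float = 10.0
    base_elevation: float = 50.0  # m
    rice_fraction: float = 0.9  # of cropland
    ndvi_baseline: float = 0.70
    evi_baseline: float = 0.50
    ndvi_depression: tuple[float, float, float] = (0.15, 0.30, 0.45)
    evi_depression: tuple[float, float, float] = (0.10, 0.20, 0.30)
    vi_noise_sd: float = 0.02
    history_years: int = 20
    history_amplitude: float = 0.05  # deterministic interannual NDVI swing
    seed: int = 0
    # region polygons in map coordinates (shapely); None -> default layout
    permanent_water: object | None = None
    stage_floods: list | None = None  # 3 polygons (nested/overlapping)
    annual_floods: list | None = None  # 5 polygons (2015..2019); 2020 = stage union
    hills: object | None = None
    confounders: list | None = None
    cropland: object | None = None

    def __post_init__(self):
        if not self.mu_water < self.mu_land:
            raise ValueError("mu_water must be below mu_land")
        if not all(
            d1 < d2 for d1, d2 in zip(self.ndvi_depression, self.ndvi_depression[1:])
        ):
            raise ValueError("ndvi_depression values must increase with intensity")
        if not 0 < self.rice_fraction <= 1:
            raise ValueError("rice_fraction must be in (0, 1]")
        h, w = self.shape
        p = self.pixel_size

        def fbox(c0, r0, c1, r1):
            # fractional (col, row) box -> map-coordinate polygon (row 0 = top)
            return box(c0 * w * p, (h - r1 * h) * p, c1 * w * p, (h - r0 * h) * p)

        # default layout: a large permanent lake (as in the lake-plain study
        # system, open water far exceeds any one flood), a nested flood belt
        # south of it, hills to the east, confounders and cropland on the plain
        if self.permanent_water is None:
            self.permanent_water = fbox(0.02, 0.02, 0.80, 0.40)
        if self.stage_floods is None:
            self.stage_floods = [
                fbox(0.20, 0.44, 0.56, 0.66),
                fbox(0.24, 0.47, 0.52, 0.63),
                fbox(0.28, 0.50, 0.47, 0.60),
            ]
        if self.annual_floods is None:
            self.annual_floods = [
                fbox(0.26, 0.46, 0.44, 0.62),
                fbox(0.28, 0.48, 0.50, 0.66),
                fbox(0.26, 0.50, 0.55, 0.72),
                fbox(0.30, 0.46, 0.48, 0.60),
                fbox(0.26, 0.48, 0.60, 0.80),
            ]
        if self.hills is None:
            self.hills = fbox(0.85, 0.0, 1.0, 1.0)
        if self.confounders is None:
            self.confounders = [fbox(0.62, 0.50, 0.67, 0.55), fbox(0.06, 0.70, 0.11, 0.75)]
        if self.cropland is None:
            self.cropland = fbox(0.05, 0.54, 0.80, 0.95)
        for g in [self.permanent_water, self.hills, self.cropland, *self.stage_floods,
                  *self.annual_floods, *self.confounders]:
            if g.is_empty or not g.is_valid:
                raise ValueError("degenerate region polygon")
        for g in self.stage_floods + self.annual_floods:
            if g.intersection(self.permanent_water).area > 0:
                raise ValueError("flood polygons must be disjoint from permanent water")

    @property
    def transform(self) -> Affine:
        h, _ = self.shape
        return Affine.from_origin(0.0, h * self.pixel_size, self.pixel_size)


@dataclass
class SceneTruth:
    """Ground truth rasters of the generated scene."""

    stage_masks: list[Raster]  # 3 binary maps
    annual_masks: list[Raster]  # 6 binary maps, 2015..2020 (last = stage union)
    permanent_water: Raster
    confounder_mask: Raster
    hill_mask: Raster
    cropland: Raster  # 0 non-crop, 1 rice, 2 other
    intensity: Raster  # 0..3 = sum of stage masks
    flood_extent: Raster  # union of stage masks (the full-period extent)


@dataclass
class ViSeries:
    """Vegetation-index inputs for damage assessment."""

    ndvi_before: Raster  # mean over the pre-flood window (Jun–Jul)
    ndvi_after: Raster  # mean over the post-flood window (Sep–Oct)
    evi_before: Raster
    evi_after: Raster
    ndvi_history: list[Raster]  # one per historical year


@dataclass
class SceneBundle:
    """Everything generate_scene produces."""

    config: SceneConfig
    ref_stack: Stack
    stage_stacks: list[Stack]
    annual_stacks: list[Stack]  # flood-period stacks for the 5 prior years
    dem: Raster
    optical: OpticalBands
    vi: ViSeries
    truth: SceneTruth
    zones: ZoneSet


def _rasterize(geom, config: SceneConfig) -> np.ndarray:
    h, w = config.shape
    rows, cols = np.mgrid[0:h, 0:w]
    x, y = config.transform.xy(rows, cols)
    return shapely.contains_xy(geom, x, y)


def _binary(mask: np.ndarray, config: SceneConfig) -> Raster:
    return Raster(mask.astype(np.uint8), config.transform, config.crs_id, NODATA_INT)


def _speckle(db: np.ndarray, looks: float | None, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Gamma speckle applied in linear power, returned in dB."""
    if looks is None or not np.isfinite(looks):
        return db
    power = 10.0 ** (db / 10.0)
    power = power * rng.gamma(shape=looks, scale=1.0 / looks, size=db.shape)
    return 10.0 * np.log10(power)


def _scene_dates(year: int, month0: int, day0: int, n: int, step: int = 6):
    d0 = _dt.date(year, month0, day0)
    return [d0 + _dt.timedelta(days=i * step) for i in range(n)]


def make_zone_grid(config: SceneConfig, nx: int = 4, ny: int = 4) -> ZoneSet:
    """Regular nx × ny grid of rectangular zones covering the scene."""
    h, w = config.shape
    p = config.pixel_size
    ids, names, geoms = [], [], []
    for i in range(ny):
        for j in range(nx):
            ids.append(f"Z{i:02d}{j:02d}")
            names.append(f"zone-{i}-{j}")
            geoms.append(
                box(j * w * p / nx, (ny - 1 - i) * h * p / ny,
                    (j + 1) * w * p / nx, (ny - i) * h * p / ny)
            )
    return ZoneSet(ids, names, geoms, crs_id=config.crs_id)


def generate_scene(config: SceneConfig) -> SceneBundle:
    """Generate SAR stacks, DEM, optical bands, VI series and ground truth."""
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    t = config.transform

    water = _rasterize(config.permanent_water, config)
    hills = _rasterize(config.hills, config)
    stage = [_rasterize(g, config) & ~water & ~hills for g in config.stage_floods]
    annual_prior = [_rasterize(g, config) & ~water & ~hills for g in config.annual_floods]
    conf = np.zeros((h, w), dtype=bool)
    for g in config.confounders:
        conf |= _rasterize(g, config)
    conf &= ~water
    for s in stage:
        conf &= ~s  # confounders are labeled non-flood
    crop_codes = np.zeros((h, w), dtype=np.uint8)
    cropland = _rasterize(config.cropland, config) & ~water & ~hills
    if cropland.any():
        # interleave crop types in column bands so both occur everywhere;
        # rice occupies rice_fraction of the cropland
        colgrid = np.arange(w)[None, :] * np.ones((h, 1), dtype=int)
        period = 20
        other = (colgrid % period) >= config.rice_fraction * period
        crop_codes[cropland & ~other] = 1
        crop_codes[cropland & other] = 2

    extent = stage[0] | stage[1] | stage[2]
    intensity = sum(s.astype(np.uint8) for s in stage)

    # --- backscatter ------------------------------------------------------
    texture = rng.normal(0.0, config.sigma, size=(h, w))
    base_land = np.where(water, config.mu_water, config.mu_land) + texture

    def draw_stack(flood_mask, dates, confound: bool):
        rasters = []
        for _ in dates:
            db = base_land.copy()
            if flood_mask is not None:
                db[flood_mask] = config.mu_water + texture[flood_mask]
            if confound:
                db[conf] = config.confounder_db + texture[conf]
            db = _speckle(db, config.looks, rng)
            rasters.append(Raster(db, t, config.crs_id))
        return Stack(rasters, dates)

    ref_stack = draw_stack(None, _scene_dates(2020, 3, 2, config.n_ref_scenes, 12), False)
    stage_windows = [(7, 1), (7, 23), (8, 14)]
    stage_stacks = [
        draw_stack(stage[k], _scene_dates(2020, *stage_windows[k], config.n_stage_scenes),
                   confound=True)
        for k in range(3)
    ]
    annual_stacks = [
        draw_stack(annual_prior[y], _scene_dates(2015 + y, 7, 5, config.n_stage_scenes),
                   confound=False)
        for y in range(5)
    ]

    # --- DEM --------------------------------------------------------------
    dem_vals = np.full((h, w), config.base_elevation, dtype=float)
    if hills.any():
        grade = np.tan(np.radians(config.hill_slope_deg)) * config.pixel_size
        cols_h = np.where(hills.any(axis=0))[0]
        colgrid = np.arange(w)[None, :]
        ramp = (colgrid - cols_h[0]) * grade
        dem_vals = np.where(hills, config.base_elevation + ramp, dem_vals)
    dem = Raster(dem_vals, t, config.crs_id)

    # --- optical bands (flood-period, Sentinel-2-like 0–10000 reflectance) -
    def band(flood_v, water_v, land_v, sd=50.0):
        vals = np.where(extent, flood_v, np.where(water, water_v, land_v)).astype(float)
        vals += rng.normal(0.0, sd, size=(h, w))
        return Raster(np.clip(vals, 0.0, None), t, config.crs_id)

    optical = OpticalBands(
        red=band(800, 500, 600),
        blue=band(400, 600, 300),
        nir=band(1500, 300, 3500),
        swir1=band(600, 150, 2200),
    )

    truth = SceneTruth(
        stage_masks=[_binary(s, config) for s in stage],
        annual_masks=[_binary(m, config) for m in annual_prior] + [_binary(extent, config)],
        permanent_water=_binary(water, config),
        confounder_mask=_binary(conf, config),
        hill_mask=_binary(hills, config),
        cropland=Raster(crop_codes, t, config.crs_id, NODATA_INT),
        intensity=Raster(intensity.astype(np.uint8), t, config.crs_id, NODATA_INT),
        flood_extent=_binary(extent, config),
    )
    vi = generate_vi_series(truth, config, rng=rng)
    return SceneBundle(
        config=config,
        ref_stack=ref_stack,
        stage_stacks=stage_stacks,
        annual_stacks=annual_stacks,
        dem=dem,
        optical=optical,
        vi=vi,
        truth=truth,
        zones=make_zone_grid(config),
    )


def generate_vi_series(
    truth: SceneTruth, config: SceneConfig, rng: np.random.Generator | None = None
) -> ViSeries:
    """Vegetation-index window means and historical NDVI series from truth.

    Post-flood indices on flooded pixels are depressed by the per-intensity
    amounts in the config; the historical series is stationary around the
    baseline (its per-pixel median ≈ baseline) with a small deterministic
    interannual swing so the condition-index denominator is well defined even
    at zero noise. Deterministic given the rng/seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    intensity = truth.intensity.values
    water = truth.permanent_water.values.astype(bool)
    t = truth.intensity.transform
    shape = truth.intensity.shape
    sd = config.vi_noise_sd

    def vi_raster(baseline, depression=None):
        vals = np.full(shape, baseline, dtype=float)
        vals[water] = 0.05
        if depression is not None:
            for k in (1, 2, 3):
                vals[intensity == k] = baseline - depression[k - 1]
        if sd > 0:
            vals += rng.normal(0.0, sd, size=shape)
        return Raster(np.clip(vals, -1.0, 1.0), t, config.crs_id)

    n_hist = config.history_years
    history = []
    for j in range(n_hist):
        swing = config.history_amplitude * np.sin(2.0 * np.pi * j / max(n_hist, 1) + 0.7)
        history.append(vi_raster(config.ndvi_baseline + swing))
    return ViSeries(
        ndvi_before=vi_raster(config.ndvi_baseline),
        ndvi_after=vi_raster(config.ndvi_baseline, config.ndvi_depression),
        evi_before=vi_raster(config.evi_baseline),
        evi_after=vi_raster(config.evi_baseline, config.evi_depression),
        ndvi_history=history,
    )


def sample_points(
    truth: SceneTruth,
    n_total: int = 3000,
    flooded_fraction: float = 0.43,
    seed: int = 0,
    train_fraction: float = 1.0 / 3.0,
) -> LabeledSampleSet:
    """Stratified flooded / non-flooded point samples with a train/val split.

    Mixed water/land edge pixels are avoided by eroding each class mask by
    one pixel before sampling; sampling is without replacement and
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    flood = truth.flood_extent.values.astype(bool)
    structure = np.ones((3, 3), dtype=bool)
    flood_core = ndimage.binary_erosion(flood, structure=structure)
    nonflood_core = ndimage.binary_erosion(~flood, structure=structure)
    n_flood = int(round(n_total * flooded_fraction))
    n_non = n_total - n_flood
    picks = []
    for mask, n, label in ((flood_core, n_flood, "flooded"), (nonflood_core, n_non, "non_flooded")):
        idx = np.flatnonzero(mask)
        if idx.size < n:
            raise ValueError(
                f"not enough eligible {label} pixels: need {n}, have {idx.size}"
            )
        chosen = rng.choice(idx, size=n, replace=False)
        rows, cols = np.unravel_index(chosen, flood.shape)
        x, y = truth.flood_extent.transform.xy(rows, cols)
        for xi, yi in zip(x, y):
            picks.append((xi, yi, label))
    order = rng.permutation(len(picks))
    n_train = int(round(n_total * train_fraction))
    rows = []
    for rank, i in enumerate(order):
        xi, yi, label = picks[i]
        rows.append((xi, yi, label, "train" if rank < n_train else "val"))
    return LabeledSampleSet.from_records(rows)
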