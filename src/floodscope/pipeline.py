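"""End-to-end orchestration on a synthetic scene: the full replay.

simulate → preprocess → per-stage synergy maps → intensity / frequency /
newly-added accounting → sample-based validation → optical cross-map →
cropland damage. Every run records a manifest (parameters, seed, resolved
thresholds, filter pixel accounting) so results are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import damage as dmg
from . import mapping as mp
from . import sar
from . import severity as sev
from . import validation as val
from .raster import Raster, Stack, NODATA_INT, area_km2, grid_percentage, write_raster
from .synthetic import SceneBundle, SceneConfig, generate_scene, sample_points

logger = logging.getLogger("floodscope")

__all__ = ["PipelineConfig", "PipelineResult", "run_end_to_end", "map_flood_period"]


@dataclass
class PipelineConfig:
    """Configuration of the synthetic end-to-end run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    threshold_route: str = "calibrated"  # "calibrated" | "auto" | "fixed"
    fixed_cdat_t: float | None = None
    fixed_ndfi_t: float | None = None
    kc: float = mp.DEFAULT_KC
    std_kind: str = "population"
    slope_cutoff_deg: float = mp.DEFAULT_SLOPE_CUTOFF_DEG
    seasonal_cutoff_db: float = mp.DEFAULT_SEASONAL_CUTOFF_DB
    filter_window: int | None = 3  # speckle filter; skipped when speckle is off
    n_samples: int = 3000
    flooded_fraction: float = 0.43
    calibration_repeats: int = 5
    grid_cell_m: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.threshold_route not in ("calibrated", "auto", "fixed"):
            raise ValueError("threshold_route must be calibrated/auto/fixed")
        if self.threshold_route == "fixed" and (
            self.fixed_cdat_t is None or self.fixed_ndfi_t is None
        ):
            raise ValueError("fixed route requires fixed_cdat_t and fixed_ndfi_t")


@dataclass
class PipelineResult:
    """Artifact bundle from one end-to-end run."""

    bundle: SceneBundle
    samples: val.LabeledSampleSet
    cdat_spec: mp.ThresholdSpec
    ndfi_spec: mp.ThresholdSpec
    stage_maps: list[Raster]  # synergy map per stage
    flood_map: Raster  # full-period synergy map
    annual_maps: list[Raster]  # 2015..2020 (last = flood_map)
    intensity: Raster
    frequency: Raster
    newly_added_map: Raster
    newly_added_km2: float
    newly_added_pct: int
    metrics: dict
    optical_map: Raster
    crossmap_r2: float
    cropland_stats: dict
    damage: dmg.DamageMap
    damage_stats: dict
    manifest: dict


def _union(maps: list[Raster]) -> Raster:
    valid = np.ones(maps[0].shape, dtype=bool)
    any_fl = np.zeros(maps[0].shape, dtype=bool)
    for m in maps:
        valid &= m.valid_mask()
        any_fl |= m.values == 1
    out = np.where(valid, any_fl.astype(np.uint8), np.uint8(NODATA_INT))
    return Raster(out, maps[0].transform, maps[0].crs_id, NODATA_INT)


def map_flood_period(
    ref_stack: Stack,
    flood_stack: Stack,
    dem: Raster,
    cdat_spec: mp.ThresholdSpec,
    ndfi_spec: mp.ThresholdSpec,
    filter_window: int | None = 3,
    accounting: dict | None = None,
) -> Raster:
    """Synergy flood map of one period with resolved thresholds."""
    ref = sar.preprocess_stack(ref_stack, filter_window)
    flo = sar.preprocess_stack(flood_stack, filter_window)
    min_r = sar.temporal_min(ref, "reference")
    min_f = sar.temporal_min(flo, "flood")
    d = mp.cdat_difference(min_f, min_r)
    nd = mp.ndfi(ref, flo)
    terrain = mp.terrain_filter(dem, cdat_spec.slope_cutoff_deg)
    background = mp.background_filter(d)
    seasonal = mp.seasonal_filter(min_f, cdat_spec.seasonal_cutoff_db)
    if accounting is not None:
        n = terrain.size
        accounting.update(
            terrain_removed=int(n - terrain.sum()),
            background_removed=int(n - background.sum()),
            seasonal_removed=int(n - seasonal.sum()),
        )
    cdat_map = mp.classify_flood(d, cdat_spec, terrain, background, seasonal)
    ndfi_map = mp.classify_flood(nd, ndfi_spec, terrain, seasonal)
    return mp.synergy_map(cdat_map, ndfi_map)


def run_end_to_end(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the complete synthetic-scene analysis; optionally write artifacts."""
    scene_cfg = dataclasses.replace(config.scene, seed=config.seed)
    logger.info("simulating scene %s @ %.0f m, seed %d", scene_cfg.shape,
                scene_cfg.pixel_size, config.seed)
    bundle = generate_scene(scene_cfg)
    fw = config.filter_window if scene_cfg.looks is not None else None

    # --- composites & full-period indices ----------------------------------
    ref = sar.preprocess_stack(bundle.ref_stack, fw)
    full_flood = bundle.stage_stacks[0].concat(bundle.stage_stacks[1]).concat(
        bundle.stage_stacks[2]
    )
    full_flood = sar.preprocess_stack(full_flood, fw)
    min_r = sar.temporal_min(ref, "reference")
    min_f = sar.temporal_min(full_flood, "flood")
    d_full = mp.cdat_difference(min_f, min_r)
    ndfi_full = mp.ndfi(ref, full_flood)

    terrain = mp.terrain_filter(bundle.dem, config.slope_cutoff_deg)
    background = mp.background_filter(d_full)
    seasonal = mp.seasonal_filter(min_f, config.seasonal_cutoff_db)
    eligibility = terrain & background & seasonal

    samples = sample_points(
        bundle.truth,
        n_total=config.n_samples,
        flooded_fraction=config.flooded_fraction,
        seed=(config.seed + 1) % 2**31,
    )

    # --- thresholds ---------------------------------------------------------
    def resolve(index, fixed_t):
        common = dict(
            kc=config.kc,
            slope_cutoff_deg=config.slope_cutoff_deg,
            seasonal_cutoff_db=config.seasonal_cutoff_db,
            std_kind=config.std_kind,
        )
        if config.threshold_route == "fixed":
            return mp.ThresholdSpec(T=fixed_t, source="fixed", **common)
        if config.threshold_route == "auto":
            return mp.adaptive_threshold(
                index, kc=config.kc, std_kind=config.std_kind, eligibility=eligibility,
                slope_cutoff_deg=config.slope_cutoff_deg,
                seasonal_cutoff_db=config.seasonal_cutoff_db,
            )
        spec = val.calibrate_threshold(
            index, samples, n_repeats=config.calibration_repeats,
            seed=(config.seed + 2) % 2**31,
        )
        return dataclasses.replace(spec, **common)

    cdat_spec = resolve(d_full, config.fixed_cdat_t)
    ndfi_spec = resolve(ndfi_full, config.fixed_ndfi_t)
    logger.info("resolved thresholds: CDAT T=%.4f, NDFI T=%.4f (%s route)",
                cdat_spec.T, ndfi_spec.T, config.threshold_route)

    # --- full-period and per-stage synergy maps -----------------------------
    accounting: dict = {}
    cdat_map = mp.classify_flood(d_full, cdat_spec, terrain, background, seasonal)
    ndfi_map = mp.classify_flood(ndfi_full, ndfi_spec, terrain, seasonal)
    flood_map = mp.synergy_map(cdat_map, ndfi_map)
    accounting["full_period"] = {
        "terrain_removed": int(terrain.size - terrain.sum()),
        "background_removed": int(terrain.size - background.sum()),
        "seasonal_removed": int(terrain.size - seasonal.sum()),
        "flooded_pixels": int(np.count_nonzero(flood_map.values == 1)),
    }

    stage_maps = []
    for k, stk in enumerate(bundle.stage_stacks):
        acct: dict = {}
        stage_maps.append(
            map_flood_period(bundle.ref_stack, stk, bundle.dem, cdat_spec, ndfi_spec,
                             fw, acct)
        )
        accounting[f"stage_{k + 1}"] = acct

    annual_maps = [
        map_flood_period(bundle.ref_stack, stk, bundle.dem, cdat_spec, ndfi_spec, fw)
        for stk in bundle.annual_stacks
    ] + [flood_map]

    # --- severity -----------------------------------------------------------
    intensity = sev.intensity_map(stage_maps)
    frequency = sev.frequency_map(annual_maps)
    new_map, new_km2, new_pct = sev.newly_added(flood_map, annual_maps[:-1])

    # --- validation ---------------------------------------------------------
    cm = val.confusion(flood_map, samples, split="val")
    metrics = val.accuracy_metrics(cm)
    metrics["confusion"] = dataclasses.asdict(cm)
    ndvi, evi, lswi = val.optical_indices(bundle.optical)
    optical_map = val.optical_flood(ndvi, evi, lswi)
    _, r2 = val.crossmap_agreement(flood_map, optical_map, bundle.zones)

    # --- cropland damage ----------------------------------------------------
    crop_mask, crop_stats = dmg.flooded_cropland(flood_map, bundle.truth.cropland)
    ndvi_d = dmg.vi_difference(bundle.vi.ndvi_after, bundle.vi.ndvi_before)
    evi_d = dmg.vi_difference(bundle.vi.evi_after, bundle.vi.evi_before)
    med, mx = dmg.historical_med_max(bundle.vi.ndvi_history)
    dvdi_r = dmg.dvdi(
        dmg.mvci(bundle.vi.ndvi_after, med, mx), dmg.mvci(bundle.vi.ndvi_before, med, mx)
    )
    on_crop = crop_mask.values == 1

    def masked(r: Raster) -> Raster:
        vals = np.where(on_crop, r.values, r.nodata)
        return r.like(vals)

    ndvi_cls, _, _ = dmg.geometric_interval_reclass(masked(ndvi_d))
    evi_cls, _, _ = dmg.geometric_interval_reclass(masked(evi_d))
    dvdi_cls, _, _ = dmg.geometric_interval_reclass(masked(dvdi_r))
    damage = dmg.severity_degree(ndvi_cls, evi_cls, dvdi_cls, intensity, on_crop)
    damage_table, damage_stats = dmg.damage_report(damage, bundle.truth.cropland,
                                                   bundle.zones)

    manifest = {
        "seed": config.seed,
        "scene": {
            k: v for k, v in dataclasses.asdict(scene_cfg).items()
            if isinstance(v, (int, float, str, tuple, list, type(None)))
        },
        "thresholds": {"CDAT": cdat_spec.to_dict(), "NDFI": ndfi_spec.to_dict()},
        "filter_accounting": accounting,
        "stage_area_km2": [area_km2(m, 1) for m in stage_maps],
        "flood_area_km2": area_km2(flood_map, 1),
    }

    result = PipelineResult(
        bundle=bundle,
        samples=samples,
        cdat_spec=cdat_spec,
        ndfi_spec=ndfi_spec,
        stage_maps=stage_maps,
        flood_map=flood_map,
        annual_maps=annual_maps,
        intensity=intensity,
        frequency=frequency,
        newly_added_map=new_map,
        newly_added_km2=new_km2,
        newly_added_pct=new_pct,
        metrics=metrics,
        optical_map=optical_map,
        crossmap_r2=r2,
        cropland_stats=crop_stats,
        damage=damage,
        damage_stats=damage_stats,
        manifest=manifest,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_raster(flood_map, outdir / "flood_2020.tif")
        for k, m in enumerate(stage_maps):
            write_raster(m, outdir / f"flood_stage{k + 1}.tif")
        write_raster(intensity, outdir / "intensity.tif")
        write_raster(frequency, outdir / "frequency.tif")
        write_raster(new_map, outdir / "newly_added_2020.tif")
        write_raster(grid_percentage(flood_map, config.grid_cell_m),
                     outdir / "flood_grid_pct.tif")
        write_raster(damage.degree, outdir / "damage_degree.tif")
        write_raster(damage.classes, outdir / "damage_classes.tif")
        samples.to_csv(outdir / "samples.csv")
        damage_table.to_csv(outdir / "damage_report.csv", index=False)
        sev.intensity_area_report(intensity, bundle.zones).to_csv(
            outdir / "intensity_by_zone.csv", index=False
        )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return result
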