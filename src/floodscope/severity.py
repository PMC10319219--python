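"""Flood-severity characterization: intensity, frequency, newly-added area.

Intensity counts how many intra-season stage maps flag a pixel (1–3);
frequency counts flooded years across a multi-year series (0–6). The
newly-added area of the current year is the flooded region never seen in
any prior year; its share is reported against the maximum ever-flooded
extent, the pixelwise union of the prior years.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster, ZoneSet, NODATA_INT, area_km2, zone_assignment

__all__ = [
    "StagePlan",
    "intensity_map",
    "frequency_map",
    "newly_added",
    "intensity_area_report",
    "round_half_away",
]

#: the three 2020 intra-season flood windows
DEFAULT_STAGES = [
    ("stage-1", _dt.date(2020, 7, 1), _dt.date(2020, 7, 22)),
    ("stage-2", _dt.date(2020, 7, 23), _dt.date(2020, 8, 13)),
    ("stage-3", _dt.date(2020, 8, 14), _dt.date(2020, 8, 31)),
]


@dataclass
class StagePlan:
    """Ordered, non-overlapping stage windows."""

    stages: list[tuple[str, _dt.date, _dt.date]]

    def __post_init__(self):
        for sid, start, end in self.stages:
            if not start <= end:
                raise ValueError(f"stage {sid}: start after end")
        for (_, _, e0), (_, s1, _) in zip(self.stages, self.stages[1:]):
            if not e0 < s1:
                raise ValueError("stage windows must be ordered and non-overlapping")

    @classmethod
    def default(cls) -> "StagePlan":
        return cls(list(DEFAULT_STAGES))


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (for printed percent shares)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def _stack_counts(maps: list[Raster], name: str) -> Raster:
    if not maps:
        raise ValueError(f"{name} requires at least one map")
    for m in maps[1:]:
        maps[0].require_same_geometry(m, name)
    valid = np.ones(maps[0].shape, dtype=bool)
    total = np.zeros(maps[0].shape, dtype=np.uint8)
    for m in maps:
        valid &= m.valid_mask()
        total = total + (m.values == 1).astype(np.uint8)
    out = np.where(valid, total, np.uint8(NODATA_INT))
    return Raster(out, maps[0].transform, maps[0].crs_id, NODATA_INT)


def intensity_map(stage_maps: list[Raster]) -> Raster:
    """Per-pixel count of flooded stages (flood intensity, 0..k)."""
    if len(stage_maps) > 3:
        warnings.warn("more than 3 stages exceeds the 1–3 intensity scheme", stacklevel=2)
    return _stack_counts(stage_maps, "intensity_map")


def frequency_map(annual_maps: list[Raster]) -> Raster:
    """Per-pixel count of flooded years (inundation frequency, 0..m)."""
    return _stack_counts(annual_maps, "frequency_map")


def newly_added(current: Raster, prior: list[Raster]) -> tuple[Raster, float, int]:
    """Newly flooded area of the current year vs the maximum ever-flooded.

    Returns (new-area map, new area in km², integer percent of the prior-year
    union). new = current AND NOT union(prior).
    """
    if not prior:
        raise ValueError("need at least one prior-year map")
    for m in prior:
        current.require_same_geometry(m, "annual maps")
    union = np.zeros(current.shape, dtype=bool)
    valid = current.valid_mask()
    for m in prior:
        valid &= m.valid_mask()
        union |= m.values == 1
    new = (current.values == 1) & ~union
    new_map = Raster(
        np.where(valid, new.astype(np.uint8), np.uint8(NODATA_INT)),
        current.transform,
        current.crs_id,
        NODATA_INT,
    )
    max_ever = Raster(
        np.where(valid, union.astype(np.uint8), np.uint8(NODATA_INT)),
        current.transform,
        current.crs_id,
        NODATA_INT,
    )
    new_km2 = area_km2(new_map, 1)
    max_km2 = area_km2(max_ever, 1)
    if max_km2 == 0:
        raise ValueError("prior-year union is empty; newly-added ratio undefined")
    return new_map, new_km2, round_half_away(100.0 * new_km2 / max_km2)


def intensity_area_report(imap: Raster, zones: ZoneSet) -> pd.DataFrame:
    """Per-zone, per-intensity-class areas (km²), long format."""
    assign = zone_assignment(imap, zones)
    px = imap.transform.pixel_area / 1e6
    valid = imap.valid_mask()
    rows = []
    for i, (zid, name) in enumerate(zip(zones.zone_ids, zones.names)):
        in_zone = (assign == i) & valid
        for k in range(0, int(imap.values[valid].max(initial=0)) + 1):
            rows.append(
                {
                    "zone_id": zid,
                    "name": name,
                    "intensity": k,
                    "area_km2": int(np.count_nonzero(in_zone & (imap.values == k))) * px,
                }
            )
    return pd.DataFrame(rows)
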