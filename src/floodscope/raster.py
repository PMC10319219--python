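"""Core geospatial data model: rasters, stacks, zones, and area accounting.

A :class:`Raster` is a 2D grid of values with an affine pixel->map transform,
a CRS identifier and a nodata sentinel. All combination operations require
identical geometry (shape, transform, CRS). Areas are computed from the
transform determinant, so a projected (metric) CRS is required for any
area-returning operation.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping as geom_mapping, shape as geom_shape

__all__ = [
    "Affine",
    "Raster",
    "Stack",
    "ZoneSet",
    "GeometryError",
    "CRSError",
    "NODATA_FLOAT",
    "NODATA_INT",
    "read_raster",
    "write_raster",
    "read_stack",
    "write_stack",
    "area_km2",
    "zonal_area",
    "grid_percentage",
]

#: nodata sentinels used throughout (continuous / categorical rasters)
NODATA_FLOAT = -9999.0
NODATA_INT = 255

#: CRS identifiers treated as geographic (degree units) -> no area computation
_GEOGRAPHIC_CRS = {"EPSG:4326", "OGC:CRS84", "CRS84", "WGS84"}


class GeometryError(ValueError):
    """Rasters combined in one operation do not share geometry."""


class CRSError(ValueError):
    """CRS missing or unsuitable for the requested operation."""


class Affine(NamedTuple):
    """Affine pixel->map transform, row-major ``(a, b, c, d, e, f)``.

    ``x = a*col + b*row + c`` and ``y = d*col + e*row + f`` with pixel
    indices measured at the upper-left corner; pixel centers are at
    ``(col + 0.5, row + 0.5)``.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, x0: float, y0: float, pixel_size: float) -> "Affine":
        """North-up grid with square pixels and top-left corner (x0, y0)."""
        return cls(pixel_size, 0.0, x0, 0.0, -pixel_size, y0)

    def xy(self, rows, cols, center: bool = True):
        """Map coordinates of pixels (arrays ok)."""
        off = 0.5 if center else 0.0
        cc = np.asarray(cols, dtype=float) + off
        rr = np.asarray(rows, dtype=float) + off
        return self.a * cc + self.b * rr + self.c, self.d * cc + self.e * rr + self.f

    def rowcol(self, x, y):
        """Inverse mapping: pixel (row, col) containing map point (x, y)."""
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise GeometryError("singular affine transform")
        dx = np.asarray(x, dtype=float) - self.c
        dy = np.asarray(y, dtype=float) - self.f
        col = (self.e * dx - self.b * dy) / det
        row = (-self.d * dx + self.a * dy) / det
        return np.floor(row).astype(int), np.floor(col).astype(int)

    @property
    def pixel_area(self) -> float:
        return abs(self.a * self.e - self.b * self.d)


@dataclass
class Raster:
    """Single-band georeferenced grid.

    Parameters
    ----------
    values : 2D array of float or integer values.
    transform : pixel->map :class:`Affine`.
    crs_id : coordinate-system identifier (e.g. ``"EPSG:32650"``; synthetic
        scenes use ``"LOCAL:m"``, a local metric frame).
    nodata : sentinel excluded from every statistic.
    """

    values: np.ndarray
    transform: Affine
    crs_id: str
    nodata: float = NODATA_FLOAT

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GeometryError("raster values must be 2D")
        if not isinstance(self.transform, Affine):
            self.transform = Affine(*self.transform)
        if self.transform.pixel_area <= 0:
            raise GeometryError("pixel width/height must be > 0")
        if not self.crs_id:
            raise CRSError("raster has no CRS identifier")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        v = self.values
        mask = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            mask &= np.isfinite(v)
        return mask

    def same_geometry(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.transform, other.transform)
            and self.crs_id == other.crs_id
        )

    def require_same_geometry(self, other: "Raster", what: str = "rasters") -> None:
        if not self.same_geometry(other):
            raise GeometryError(f"{what} do not share shape/transform/CRS")

    def is_projected(self) -> bool:
        return self.crs_id.upper() not in _GEOGRAPHIC_CRS

    def like(self, values: np.ndarray, nodata=None) -> "Raster":
        """New raster on this grid with different values."""
        return Raster(
            values,
            self.transform,
            self.crs_id,
            self.nodata if nodata is None else nodata,
        )

    def pixel_centers(self):
        """(x, y) arrays of all pixel centers, shape == raster shape."""
        rows, cols = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        return self.transform.xy(rows, cols)

    def sample(self, x, y):
        """Values at map coordinates; points off the grid raise IndexError."""
        row, col = self.transform.rowcol(x, y)
        if np.any((row < 0) | (row >= self.shape[0]) | (col < 0) | (col >= self.shape[1])):
            raise IndexError("sample point outside raster extent")
        return self.values[row, col]


def _check_categories(raster: Raster, allowed: Iterable[int], name: str) -> Raster:
    allowed = set(int(a) for a in allowed)
    vals = raster.values[raster.valid_mask()]
    bad = set(np.unique(vals).tolist()) - allowed
    if bad:
        raise ValueError(f"{name} contains values outside {sorted(allowed)}: {sorted(bad)}")
    return raster


def as_binary_flood_map(raster: Raster) -> Raster:
    return _check_categories(raster, {0, 1}, "BinaryFloodMap")


def as_intensity_map(raster: Raster) -> Raster:
    return _check_categories(raster, {0, 1, 2, 3}, "IntensityMap")


def as_frequency_map(raster: Raster) -> Raster:
    return _check_categories(raster, range(7), "FrequencyMap")


@dataclass
class Stack:
    """Time-ordered, co-registered rasters (e.g. a reference or flood period)."""

    rasters: list[Raster]
    timestamps: list[_dt.date]

    def __post_init__(self):
        if len(self.rasters) != len(self.timestamps):
            raise ValueError("one timestamp per raster required")
        for t0, t1 in zip(self.timestamps, self.timestamps[1:]):
            if not t1 > t0:
                raise ValueError("timestamps must be strictly increasing")
        for r in self.rasters[1:]:
            self.rasters[0].require_same_geometry(r, "stack members")

    def __len__(self) -> int:
        return len(self.rasters)

    @property
    def first(self) -> Raster:
        if not self.rasters:
            raise ValueError("empty stack")
        return self.rasters[0]

    def concat(self, other: "Stack") -> "Stack":
        """Concatenation of two stacks (order preserved, dates merged)."""
        self.first.require_same_geometry(other.first, "stacks")
        pairs = sorted(
            zip(self.timestamps + other.timestamps, self.rasters + other.rasters),
            key=lambda p: p[0],
        )
        # allow duplicate dates across stacks by nudging ordering only
        rasters = [p[1] for p in pairs]
        dates = [p[0] for p in pairs]
        stk = object.__new__(Stack)
        stk.rasters = rasters
        stk.timestamps = dates
        return stk


@dataclass
class ZoneSet:
    """Named polygons (counties, grid cells) in the raster CRS."""

    zone_ids: list[str]
    names: list[str]
    geometries: list  # shapely geometries
    crs_id: str = "LOCAL:m"

    def __post_init__(self):
        if len(set(self.zone_ids)) != len(self.zone_ids):
            raise ValueError("zone_id values must be unique")
        if not (len(self.zone_ids) == len(self.names) == len(self.geometries)):
            raise ValueError("zone_ids, names, geometries must align")

    def __len__(self) -> int:
        return len(self.zone_ids)

    @classmethod
    def from_geojson(cls, path, crs_id: str = "LOCAL:m") -> "ZoneSet":
        with open(path) as fh:
            fc = json.load(fh)
        ids, names, geoms = [], [], []
        for feat in fc["features"]:
            props = feat.get("properties", {})
            ids.append(str(props["zone_id"]))
            names.append(str(props.get("name", props["zone_id"])))
            geoms.append(geom_shape(feat["geometry"]))
        return cls(ids, names, geoms, crs_id=crs_id)

    def to_geojson(self, path) -> None:
        feats = [
            {
                "type": "Feature",
                "properties": {"zone_id": zid, "name": name},
                "geometry": geom_mapping(geom),
            }
            for zid, name, geom in zip(self.zone_ids, self.names, self.geometries)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# I/O — single-band and multi-band TIFF with JSON georeferencing metadata
# ---------------------------------------------------------------------------

def _meta_json(transform: Affine, crs_id: str, nodata, dates=None) -> str:
    meta = {
        "transform": list(map(float, transform)),
        "crs_id": crs_id,
        "nodata": None if nodata is None else float(nodata),
    }
    if dates is not None:
        meta["dates"] = [d.isoformat() for d in dates]
    return json.dumps(meta)


def _read_meta(path):
    with tifffile.TiffFile(path) as tif:
        desc = tif.pages[0].description
        data = tif.asarray()
    if not desc:
        raise CRSError(f"{path}: no georeferencing metadata (CRS missing)")
    try:
        meta = json.loads(desc)
        transform = Affine(*meta["transform"])
        crs_id = meta["crs_id"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise CRSError(f"{path}: unreadable georeferencing metadata") from exc
    return data, meta, transform, crs_id


def write_raster(raster: Raster, path) -> None:
    """Write a single-band TIFF (float32 for continuous, uint8 for categorical)."""
    vals = raster.values
    if np.issubdtype(vals.dtype, np.integer):
        out = vals.astype(np.uint8)
    else:
        out = vals.astype(np.float32)
    tifffile.imwrite(
        path,
        out,
        description=_meta_json(raster.transform, raster.crs_id, raster.nodata),
        metadata=None,
    )


def read_raster(path) -> Raster:
    data, meta, transform, crs_id = _read_meta(path)
    if data.ndim != 2:
        raise GeometryError(f"{path}: expected single band, got shape {data.shape}")
    nodata = meta.get("nodata")
    if nodata is None:
        nodata = NODATA_FLOAT
    if np.issubdtype(data.dtype, np.integer):
        nodata = int(nodata)
    return Raster(data, transform, crs_id, nodata)


def write_stack(stack: Stack, path) -> None:
    """Write a multi-band TIFF, band order = time order, ISO dates in metadata."""
    arr = np.stack([r.values.astype(np.float32) for r in stack.rasters])
    r0 = stack.first
    tifffile.imwrite(
        path,
        arr,
        photometric="minisblack",
        description=_meta_json(r0.transform, r0.crs_id, r0.nodata, stack.timestamps),
        metadata=None,
    )


def read_stack(path) -> Stack:
    data, meta, transform, crs_id = _read_meta(path)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected multi-band stack, got shape {data.shape}")
    dates = [_dt.date.fromisoformat(d) for d in meta["dates"]]
    nodata = meta.get("nodata", NODATA_FLOAT)
    rasters = [Raster(band, transform, crs_id, nodata) for band in data]
    return Stack(rasters, dates)


# ---------------------------------------------------------------------------
# Area accounting
# ---------------------------------------------------------------------------

def _require_metric(raster: Raster) -> None:
    if not raster.is_projected():
        raise CRSError(
            f"area requires a projected (metric) CRS; got {raster.crs_id!r} — "
            "project the raster to a metric CRS first"
        )


def area_km2(cat_map: Raster, category: int) -> float:
    """Area of one category in km² (pixel count × pixel area)."""
    _require_metric(cat_map)
    count = int(np.count_nonzero((cat_map.values == category) & cat_map.valid_mask()))
    return count * cat_map.transform.pixel_area / 1e6


def zone_assignment(cat_map: Raster, zones: ZoneSet) -> np.ndarray:
    """Index of the zone containing each pixel center (-1 = no zone).

    Each pixel belongs to exactly one zone: the first zone (in ZoneSet
    order) whose polygon contains the pixel center point.
    """
    x, y = cat_map.pixel_centers()
    assign = np.full(cat_map.shape, -1, dtype=int)
    for i, geom in enumerate(zones.geometries):
        hit = shapely.contains_xy(geom, x, y) & (assign == -1)
        assign[hit] = i
    return assign


def zonal_area(cat_map: Raster, zones: ZoneSet, category: int) -> pd.DataFrame:
    """Per-zone area of one category in km² (pixel-center-in-zone rule)."""
    _require_metric(cat_map)
    assign = zone_assignment(cat_map, zones)
    if not np.any(assign >= 0):
        warnings.warn("zones do not intersect the raster extent", stacklevel=2)
        return pd.DataFrame({"zone_id": [], "name": [], "area_km2": []})
    sel = (cat_map.values == category) & cat_map.valid_mask()
    px = cat_map.transform.pixel_area / 1e6
    rows = []
    for i, (zid, name) in enumerate(zip(zones.zone_ids, zones.names)):
        rows.append(
            {
                "zone_id": zid,
                "name": name,
                "area_km2": int(np.count_nonzero(sel & (assign == i))) * px,
            }
        )
    return pd.DataFrame(rows)


def grid_percentage(flood_map: Raster, cell_size_m: float) -> Raster:
    """Coarse-grid percentage of flooded pixels per cell (e.g. 10 km cells).

    Each coarse cell gets ``100 × flooded / valid`` over the fine pixels it
    covers; cells with no valid pixel are nodata. The cell size must be an
    integer multiple of the pixel size.
    """
    _require_metric(flood_map)
    t = flood_map.transform
    if abs(t.b) > 0 or abs(t.d) > 0:
        raise GeometryError("grid_percentage requires an axis-aligned transform")
    px_w, px_h = abs(t.a), abs(t.e)
    fx, fy = cell_size_m / px_w, cell_size_m / px_h
    if abs(fx - round(fx)) > 1e-9 or abs(fy - round(fy)) > 1e-9:
        raise GeometryError("cell size must be an integer multiple of the pixel size")
    fx, fy = int(round(fx)), int(round(fy))
    h, w = flood_map.shape
    ny, nx = int(np.ceil(h / fy)), int(np.ceil(w / fx))
    valid = flood_map.valid_mask()
    flooded = (flood_map.values == 1) & valid
    out = np.full((ny, nx), NODATA_FLOAT, dtype=float)
    for i in range(ny):
        for j in range(nx):
            v = valid[i * fy : (i + 1) * fy, j * fx : (j + 1) * fx]
            f = flooded[i * fy : (i + 1) * fy, j * fx : (j + 1) * fx]
            n = int(v.sum())
            if n:
                out[i, j] = 100.0 * int(f.sum()) / n
    coarse = Affine(t.a * fx, 0.0, t.c, 0.0, t.e * fy, t.f)
    return Raster(out, coarse, flood_map.crs_id, NODATA_FLOAT)
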