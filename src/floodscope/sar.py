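"""Backscatter preprocessing and temporal compositing.

SAR backscatter arrives as linear power and is analysed in decibels
(``10·log10``). Scenes are speckle-filtered individually (focal median,
nodata-aware), then composited over time: per-pixel minimum for the flood
signal (open water is dark in every look that catches it) and per-pixel
mean for the reference baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .raster import Raster, Stack, NODATA_FLOAT

__all__ = [
    "CompositeRaster",
    "to_decibel",
    "speckle_filter",
    "temporal_min",
    "temporal_mean",
    "preprocess_stack",
]


@dataclass
class CompositeRaster:
    """A temporal composite tagged with its statistic and source period."""

    raster: Raster
    statistic: str  # "min" | "mean"
    period: str = ""  # e.g. "reference", "flood-stage-1"

    def __post_init__(self):
        if self.statistic not in ("min", "mean"):
            raise ValueError(f"statistic must be 'min' or 'mean', got {self.statistic!r}")


def to_decibel(linear: Raster) -> Raster:
    """dB = 10·log10(x); nonpositive or invalid power becomes nodata."""
    vals = linear.values
    ok = linear.valid_mask() & (vals > 0)
    out = np.full(linear.shape, NODATA_FLOAT, dtype=float)
    out[ok] = 10.0 * np.log10(vals[ok])
    return Raster(out, linear.transform, linear.crs_id, NODATA_FLOAT)


def speckle_filter(raster: Raster, window: int = 3) -> Raster:
    """Focal median despeckling; nodata pixels are excluded from neighborhoods.

    Pixels that are nodata stay nodata. The window must be odd and >= 3.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    valid = raster.valid_mask()
    work = np.where(valid, raster.values.astype(float), np.nan)
    pad = window // 2
    padded = np.pad(work, pad, mode="constant", constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    with np.errstate(all="ignore"):
        med = np.nanmedian(win.reshape(*raster.shape, -1), axis=-1)
    out = np.full(raster.shape, raster.nodata, dtype=float)
    out[valid] = med[valid]
    return Raster(out, raster.transform, raster.crs_id, raster.nodata)


def _temporal(stack: Stack, statistic: str, period: str) -> CompositeRaster:
    if len(stack) == 0:
        raise ValueError("empty stack")
    r0 = stack.first
    cube = np.stack(
        [np.where(r.valid_mask(), r.values.astype(float), np.nan) for r in stack.rasters]
    )
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels -> nodata
        agg = np.nanmin(cube, axis=0) if statistic == "min" else np.nanmean(cube, axis=0)
    out = np.where(np.isnan(agg), NODATA_FLOAT, agg)
    return CompositeRaster(Raster(out, r0.transform, r0.crs_id, NODATA_FLOAT), statistic, period)


def temporal_min(stack: Stack, period: str = "") -> CompositeRaster:
    """Per-pixel minimum over valid observations; all-nodata pixels stay nodata."""
    return _temporal(stack, "min", period)


def temporal_mean(stack: Stack, period: str = "") -> CompositeRaster:
    """Per-pixel mean over valid observations; all-nodata pixels stay nodata."""
    return _temporal(stack, "mean", period)


def preprocess_stack(stack: Stack, filter_window: int | None = 3) -> Stack:
    """Speckle-filter each scene before compositing (set window=None to skip)."""
    if filter_window is None:
        return stack
    return Stack(
        [speckle_filter(r, filter_window) for r in stack.rasters], list(stack.timestamps)
    )
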