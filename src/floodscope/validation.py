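"""Accuracy assessment and sample-based threshold calibration.

Flood maps are assessed against labeled point samples with a two-class
confusion matrix (flooded = positive class) and the standard thematic-map
accuracies: overall accuracy (OA), user's accuracy (UA, precision per
class), producer's accuracy (PA, recall per class) and the F1 score of the
flooded class. An optical (Sentinel-2-style) flood rule — flooded where
``LSWI > EVI`` and ``NDVI > 0.1`` — provides an independent cross-map whose
county-level agreement with the SAR map is summarised by an OLS R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import ChangeIndexRaster, ThresholdSpec
from .raster import Raster, ZoneSet, NODATA_FLOAT, NODATA_INT, zonal_area

__all__ = [
    "LabeledSampleSet",
    "ConfusionMatrix",
    "OpticalBands",
    "calibrate_threshold",
    "confusion",
    "accuracy_metrics",
    "optical_indices",
    "optical_flood",
    "crossmap_agreement",
]

_LABELS = {"flooded", "non_flooded"}
_SPLITS = {"train", "val"}


@dataclass
class LabeledSampleSet:
    """Point samples with flooded / non-flooded labels and a train/val split."""

    table: pd.DataFrame  # columns: x, y, label, split

    def __post_init__(self):
        missing = {"x", "y", "label", "split"} - set(self.table.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if not set(self.table["label"]).issubset(_LABELS):
            raise ValueError(f"labels must be in {_LABELS}")
        if not set(self.table["split"]).issubset(_SPLITS):
            raise ValueError(f"splits must be in {_SPLITS}")

    @classmethod
    def from_records(cls, rows) -> "LabeledSampleSet":
        return cls(pd.DataFrame(rows, columns=["x", "y", "label", "split"]))

    @classmethod
    def from_csv(cls, path) -> "LabeledSampleSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def subset(self, split: str | None = None) -> pd.DataFrame:
        if split is None:
            return self.table
        return self.table[self.table["split"] == split]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ConfusionMatrix:
    """Two-class counts, flooded = positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class OpticalBands:
    """Co-registered reflectance bands scaled 0–10000."""

    red: Raster
    blue: Raster
    nir: Raster
    swir1: Raster

    def __post_init__(self):
        for b in (self.blue, self.nir, self.swir1):
            self.red.require_same_geometry(b, "optical bands")


def _sample_index_values(index: ChangeIndexRaster, samples: pd.DataFrame):
    r = index.raster
    vals = r.sample(samples["x"].to_numpy(), samples["y"].to_numpy())
    labels = (samples["label"] == "flooded").to_numpy()
    ok = vals != r.nodata
    return np.asarray(vals, dtype=float)[ok], labels[ok]


def _best_threshold(train_vals, cand=None):
    """Candidate thresholds covering every distinct strict-< classification."""
    if cand is None:
        cand = np.unique(train_vals)
        cand = np.concatenate([cand, [cand[-1] + 1.0]])
    return cand


def _oa(vals, labels, t) -> float:
    pred = vals < t
    return float(np.mean(pred == labels))


def calibrate_threshold(
    index: ChangeIndexRaster,
    samples: LabeledSampleSet,
    n_repeats: int = 5,
    seed: int = 0,
    train_fraction: float = 1.0 / 3.0,
) -> ThresholdSpec:
    """Sample-based threshold: repeated train/val re-partition + exhaustive search.

    Each repeat re-partitions the samples into train/validation at the given
    proportions, searches thresholds over the unique train index values
    (every distinct classification reachable with the strict ``index < T``
    rule) for the best training OA, and scores it on the validation split;
    the repeat whose threshold validates best wins. Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    vals, labels = _sample_index_values(index, samples.table)
    if labels.all() or not labels.any():
        raise ValueError("calibration requires both flooded and non-flooded samples")
    if np.unique(vals).size == 1:
        warnings.warn("all samples share one index value; degenerate threshold", stacklevel=2)
        return ThresholdSpec(T=float(vals[0]), source="calibrated")
    n = len(vals)
    n_train = max(1, int(round(n * train_fraction)))
    best_t, best_val_oa = None, -1.0
    for _ in range(n_repeats):
        order = rng.permutation(n)
        tr, va = order[:n_train], order[n_train:]
        if np.unique(labels[tr]).size < 2 or np.unique(labels[va]).size < 2:
            continue
        cands = _best_threshold(vals[tr])
        train_oas = [_oa(vals[tr], labels[tr], t) for t in cands]
        t_star = float(cands[int(np.argmax(train_oas))])
        # center the threshold in the decision gap: any T in (prev, t*] yields
        # the same classification on the train samples, and the midpoint is
        # more robust when applied to unseen pixels
        below = vals[tr][vals[tr] < t_star]
        if below.size:
            t_star = 0.5 * (float(below.max()) + t_star)
        val_oa = _oa(vals[va], labels[va], t_star)
        if val_oa > best_val_oa:
            best_val_oa, best_t = val_oa, t_star
    if best_t is None:
        raise ValueError("could not form two-class train/validation partitions")
    return ThresholdSpec(T=best_t, source="calibrated")


def confusion(pred: Raster, samples: LabeledSampleSet, split: str | None = "val") -> ConfusionMatrix:
    """Confusion matrix of a binary flood map at the sample points."""
    tab = samples.subset(split)
    vals = pred.sample(tab["x"].to_numpy(), tab["y"].to_numpy())
    vals = np.asarray(vals)
    ok = vals != pred.nodata
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{n_bad} samples fell on nodata pixels and were excluded", stacklevel=2)
    pred_fl = vals[ok] == 1
    truth_fl = (tab["label"].to_numpy() == "flooded")[ok]
    return ConfusionMatrix(
        tp=int(np.count_nonzero(pred_fl & truth_fl)),
        fp=int(np.count_nonzero(pred_fl & ~truth_fl)),
        fn=int(np.count_nonzero(~pred_fl & truth_fl)),
        tn=int(np.count_nonzero(~pred_fl & ~truth_fl)),
    )


def accuracy_metrics(cm: ConfusionMatrix) -> dict:
    """OA / UA / PA per class (percent) and the flooded-class F1 score.

    Undefined ratios (zero denominators) are returned as NaN.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    oa = pct(cm.tp + cm.tn, cm.total)
    ua_fl = pct(cm.tp, cm.tp + cm.fp)
    pa_fl = pct(cm.tp, cm.tp + cm.fn)
    ua_nf = pct(cm.tn, cm.tn + cm.fn)
    pa_nf = pct(cm.tn, cm.tn + cm.fp)
    p, r = ua_fl / 100.0, pa_fl / 100.0
    f1 = 2 * p * r / (p + r) if np.isfinite(p) and np.isfinite(r) and (p + r) > 0 else float("nan")
    return {
        "OA": oa,
        "UA_flooded": ua_fl,
        "PA_flooded": pa_fl,
        "UA_nonflooded": ua_nf,
        "PA_nonflooded": pa_nf,
        "F1": f1,
    }


def optical_indices(bands: OpticalBands) -> tuple[Raster, Raster, Raster]:
    """NDVI, EVI, LSWI from 0–10000-scaled reflectance.

    EVI uses the canopy-background/aerosol constant on the reflectance scale
    (``+10000``; use ``scale=1.0`` rasters and ``+1`` upstream for 0–1 data).
    """
    red, blue, nir, swir1 = (
        bands.red.values.astype(float),
        bands.blue.values.astype(float),
        bands.nir.values.astype(float),
        bands.swir1.values.astype(float),
    )
    like = bands.red

    def ratio(num, den):
        out = np.full(like.shape, NODATA_FLOAT, dtype=float)
        ok = den != 0
        out[ok] = num[ok] / den[ok]
        return Raster(out, like.transform, like.crs_id, NODATA_FLOAT)

    ndvi = ratio(nir - red, nir + red)
    evi = ratio(2.5 * (nir - red), nir + 6.0 * red - 7.5 * blue + 10000.0)
    lswi = ratio(nir - swir1, nir + swir1)
    return ndvi, evi, lswi


def optical_flood(ndvi: Raster, evi: Raster, lswi: Raster) -> Raster:
    """Optical flood rule: flooded where LSWI > EVI and NDVI > 0.1 (strict)."""
    ndvi.require_same_geometry(evi, "indices")
    ndvi.require_same_geometry(lswi, "indices")
    ok = ndvi.valid_mask() & evi.valid_mask() & lswi.valid_mask()
    flooded = (lswi.values > evi.values) & (ndvi.values > 0.1)
    out = np.where(ok, flooded.astype(np.uint8), np.uint8(NODATA_INT))
    return Raster(out, ndvi.transform, ndvi.crs_id, NODATA_INT)


def crossmap_agreement(
    map_a: Raster, map_b: Raster, zones: ZoneSet
) -> tuple[pd.DataFrame, float]:
    """Per-zone flooded areas of two maps and the OLS R² of B on A.

    Returns (table with columns zone_id, area_a_km2, area_b_km2; R²). A
    zero-variance area vector makes R² undefined (NaN, with a warning).
    """
    if len(zones) < 2:
        raise ValueError("need at least two zones")
    ta = zonal_area(map_a, zones, 1).rename(columns={"area_km2": "area_a_km2"})
    tb = zonal_area(map_b, zones, 1).rename(columns={"area_km2": "area_b_km2"})
    tab = ta.merge(tb[["zone_id", "area_b_km2"]], on="zone_id")
    a = tab["area_a_km2"].to_numpy()
    b = tab["area_b_km2"].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero-variance zonal areas; R² undefined", stacklevel=2)
        return tab, float("nan")
    res = stats.linregress(a, b)
    return tab, float(res.rvalue**2)
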