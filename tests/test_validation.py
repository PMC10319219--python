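"""Accuracy metrics, threshold calibration and the optical cross-map."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from floodscope.mapping import ChangeIndexRaster
from floodscope.raster import ZoneSet, NODATA_INT
from floodscope.validation import (
    ConfusionMatrix,
    LabeledSampleSet,
    OpticalBands,
    accuracy_metrics,
    calibrate_threshold,
    confusion,
    crossmap_agreement,
    optical_flood,
    optical_indices,
)

from conftest import make_binary, make_raster


def _samples_on_grid(raster, labels_by_pixel, split="val"):
    rows = []
    for (i, j), label in labels_by_pixel.items():
        x, y = raster.transform.xy(i, j)
        rows.append((float(x), float(y), label, split))
    return LabeledSampleSet.from_records(rows)


class TestAccuracyMetrics:
    def test_perfect_classifier(self):
        m = accuracy_metrics(ConfusionMatrix(tp=40, fp=0, fn=0, tn=60))
        assert m["OA"] == 100.0 and m["F1"] == 1.0

    def test_matches_hand_formulas(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 500, size=4)
            m = accuracy_metrics(ConfusionMatrix(int(tp), int(fp), int(fn), int(tn)))
            total = tp + fp + fn + tn
            assert m["OA"] == pytest.approx(100 * (tp + tn) / total)
            assert m["UA_flooded"] == pytest.approx(100 * tp / (tp + fp))
            assert m["PA_flooded"] == pytest.approx(100 * tp / (tp + fn))
            assert m["UA_nonflooded"] == pytest.approx(100 * tn / (tn + fn))
            assert m["PA_nonflooded"] == pytest.approx(100 * tn / (tn + fp))
            p, r = tp / (tp + fp), tp / (tp + fn)
            assert m["F1"] == pytest.approx(2 * p * r / (p + r))

    def test_undefined_ratio_flagged_as_nan(self):
        m = accuracy_metrics(ConfusionMatrix(tp=0, fp=0, fn=5, tn=5))
        assert np.isnan(m["UA_flooded"])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accuracy_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 1)


class TestConfusion:
    def test_perfect_prediction_no_errors(self):
        pred = make_binary([[1, 1], [0, 0]])
        s = _samples_on_grid(pred, {(0, 0): "flooded", (0, 1): "flooded",
                                    (1, 0): "non_flooded", (1, 1): "non_flooded"})
        cm = confusion(pred, s)
        assert cm.fp == 0 and cm.fn == 0 and cm.tp == 2 and cm.tn == 2

    def test_inverted_prediction(self):
        pred = make_binary([[0, 0], [1, 1]])
        s = _samples_on_grid(pred, {(0, 0): "flooded", (0, 1): "flooded",
                                    (1, 0): "non_flooded", (1, 1): "non_flooded"})
        cm = confusion(pred, s)
        assert cm.tp == 0 and cm.tn == 0 and cm.fp == 2 and cm.fn == 2

    def test_matches_point_loop(self, rng):
        vals = rng.integers(0, 2, size=(12, 12)).astype(np.uint8)
        pred = make_binary(vals)
        labels = {}
        for _ in range(40):
            i, j = rng.integers(0, 12, size=2)
            labels[(int(i), int(j))] = "flooded" if rng.random() < 0.5 else "non_flooded"
        s = _samples_on_grid(pred, labels)
        cm = confusion(pred, s)
        tp = fp = fn = tn = 0
        for (i, j), lab in labels.items():
            p, t = vals[i, j] == 1, lab == "flooded"
            tp += p and t; fp += p and not t; fn += (not p) and t; tn += (not p) and not t
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)

    def test_nodata_samples_excluded_with_warning(self):
        vals = np.array([[1, NODATA_INT], [0, 0]], dtype=np.uint8)
        pred = make_binary(vals)
        s = _samples_on_grid(pred, {(0, 0): "flooded", (0, 1): "flooded"})
        with pytest.warns(UserWarning):
            cm = confusion(pred, s)
        assert cm.total == 1


class TestCalibration:
    def _index_and_samples(self, rng, n=300, gap=(-5.0, -1.0)):
        """Index raster with flooded values < gap[0] and non-flooded > gap[1]."""
        vals = np.zeros((30, 30))
        labels = {}
        cells = [(i, j) for i in range(30) for j in range(30)]
        rng.shuffle(cells)
        for k, (i, j) in enumerate(cells[:n]):
            if k < n // 2:
                vals[i, j] = gap[0] - 1 - rng.random() * 3
                labels[(i, j)] = "flooded"
            else:
                vals[i, j] = gap[1] + 1 + rng.random() * 3
                labels[(i, j)] = "non_flooded"
        idx = ChangeIndexRaster(make_raster(vals), "CDAT")
        return idx, _samples_on_grid(idx.raster, labels)

    def test_separable_classes_recovered_exactly(self, rng):
        idx, samples = self._index_and_samples(rng)
        spec = calibrate_threshold(idx, samples, seed=1)
        assert -6.0 <= spec.T <= -0.9
        vals = idx.raster.sample(samples.table["x"].to_numpy(), samples.table["y"].to_numpy())
        pred = vals < spec.T
        truth = (samples.table["label"] == "flooded").to_numpy()
        assert (pred == truth).all()

    def test_deterministic_given_seed(self, rng):
        idx, samples = self._index_and_samples(rng)
        t1 = calibrate_threshold(idx, samples, seed=7).T
        t2 = calibrate_threshold(idx, samples, seed=7).T
        assert t1 == t2

    def test_degenerate_constant_index_warns(self):
        vals = np.full((10, 10), -3.0)
        idx = ChangeIndexRaster(make_raster(vals), "CDAT")
        labels = {(0, 0): "flooded", (5, 5): "non_flooded", (2, 7): "flooded",
                  (7, 2): "non_flooded", (3, 3): "flooded", (6, 6): "non_flooded"}
        samples = _samples_on_grid(idx.raster, labels)
        with pytest.warns(UserWarning):
            spec = calibrate_threshold(idx, samples, seed=1)
        assert spec.T == -3.0

    def test_single_class_rejected(self):
        idx = ChangeIndexRaster(make_raster(np.zeros((5, 5))), "CDAT")
        samples = _samples_on_grid(idx.raster, {(0, 0): "flooded", (1, 1): "flooded"})
        with pytest.raises(ValueError):
            calibrate_threshold(idx, samples, seed=1)


class TestOptical:
    def test_ndvi_zero_when_nir_equals_red(self):
        bands = OpticalBands(
            red=make_raster(np.full((2, 2), 2000.0)),
            blue=make_raster(np.full((2, 2), 500.0)),
            nir=make_raster(np.full((2, 2), 2000.0)),
            swir1=make_raster(np.full((2, 2), 1000.0)),
        )
        ndvi, _, _ = optical_indices(bands)
        assert ndvi.values[0, 0] == 0.0

    def test_evi_lswi_closed_form(self):
        bands = OpticalBands(
            red=make_raster(np.full((2, 2), 1000.0)),
            blue=make_raster(np.full((2, 2), 500.0)),
            nir=make_raster(np.full((2, 2), 4000.0)),
            swir1=make_raster(np.full((2, 2), 2000.0)),
        )
        _, evi, lswi = optical_indices(bands)
        assert evi.values[0, 0] == pytest.approx(2.5 * 3000 / (4000 + 6000 - 3750 + 10000))
        assert evi.values[0, 0] == pytest.approx(7500 / 16250)
        assert lswi.values[0, 0] == pytest.approx(1 / 3)

    def test_indices_match_elementwise_formulas(self, rng):
        red, blue = rng.uniform(100, 3000, (6, 6)), rng.uniform(100, 1500, (6, 6))
        nir, swir1 = rng.uniform(100, 5000, (6, 6)), rng.uniform(100, 3000, (6, 6))
        bands = OpticalBands(*(make_raster(b) for b in (red, blue, nir, swir1)))
        ndvi, evi, lswi = optical_indices(bands)
        np.testing.assert_allclose(ndvi.values, (nir - red) / (nir + red), atol=1e-12)
        np.testing.assert_allclose(
            evi.values, 2.5 * (nir - red) / (nir + 6 * red - 7.5 * blue + 10000), atol=1e-12
        )
        np.testing.assert_allclose(lswi.values, (nir - swir1) / (nir + swir1), atol=1e-12)

    @pytest.mark.parametrize(
        "lswi,evi,ndvi,flooded",
        [
            (0.2, 0.1, 0.3, 1),   # rule satisfied
            (0.2, 0.1, 0.05, 0),  # NDVI too low
            (0.1, 0.2, 0.3, 0),   # LSWI not above EVI
            (0.2, 0.1, 0.1, 0),   # NDVI exactly at 0.1: strict inequality
            (0.2, 0.2, 0.3, 0),   # LSWI exactly equal: strict inequality
        ],
    )
    def test_flood_rule_boundaries(self, lswi, evi, ndvi, flooded):
        out = optical_flood(
            make_raster(np.full((2, 2), ndvi)),
            make_raster(np.full((2, 2), evi)),
            make_raster(np.full((2, 2), lswi)),
        )
        assert out.values[0, 0] == flooded

    def test_flood_rule_matches_bruteforce(self, rng):
        ndvi = make_raster(rng.uniform(-0.2, 0.8, (10, 10)))
        evi = make_raster(rng.uniform(-0.2, 0.8, (10, 10)))
        lswi = make_raster(rng.uniform(-0.2, 0.8, (10, 10)))
        out = optical_flood(ndvi, evi, lswi)
        expected = (lswi.values > evi.values) & (ndvi.values > 0.1)
        np.testing.assert_array_equal(out.values == 1, expected)


class TestCrossmap:
    def _zones(self, n=4, size=40, px=10.0):
        side = size * px / n
        ids, geoms = [], []
        for i in range(n):
            for j in range(n):
                ids.append(f"z{i}{j}")
                geoms.append(box(j * side, i * side, (j + 1) * side, (i + 1) * side))
        return ZoneSet(ids, ids, geoms)

    def test_identical_maps_r2_one(self, rng):
        vals = rng.integers(0, 2, size=(40, 40)).astype(np.uint8)
        m = make_binary(vals)
        _, r2 = crossmap_agreement(m, make_binary(vals.copy()), self._zones())
        assert r2 == pytest.approx(1.0)

    def test_empty_map_r2_undefined(self, rng):
        a = make_binary(rng.integers(0, 2, size=(40, 40)))
        b = make_binary(np.zeros((40, 40)))
        with pytest.warns(UserWarning):
            _, r2 = crossmap_agreement(a, b, self._zones())
        assert np.isnan(r2)

    def test_matches_textbook_r2(self, rng):
        a = make_binary(rng.integers(0, 2, size=(40, 40)))
        b = make_binary(rng.integers(0, 2, size=(40, 40)))
        tab, r2 = crossmap_agreement(a, b, self._zones())
        x = tab["area_a_km2"].to_numpy()
        y = tab["area_b_km2"].to_numpy()
        expected = np.corrcoef(x, y)[0, 1] ** 2
        assert r2 == pytest.approx(expected)

    def test_too_few_zones_rejected(self):
        m = make_binary(np.ones((4, 4)))
        with pytest.raises(ValueError):
            crossmap_agreement(m, m, ZoneSet(["z"], ["z"], [box(0, 0, 40, 40)]))
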