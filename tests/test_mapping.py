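"""Change indices, adaptive threshold, filter cascade and synergy map."""

import datetime as dt

import numpy as np
import pytest

from floodscope.mapping import (
    ChangeIndexRaster,
    ThresholdSpec,
    adaptive_threshold,
    background_filter,
    cdat_difference,
    classify_flood,
    horn_slope,
    ndfi,
    seasonal_filter,
    synergy_map,
    terrain_filter,
)
from floodscope.raster import Stack, NODATA_FLOAT, area_km2
from floodscope.sar import CompositeRaster, temporal_min

from conftest import make_binary, make_raster


def _stack(arrays):
    rs = [make_raster(np.asarray(a, dtype=float)) for a in arrays]
    dates = [dt.date(2020, 7, 1) + dt.timedelta(days=6 * i) for i in range(len(rs))]
    return Stack(rs, dates)


def _min_comp(values):
    return CompositeRaster(make_raster(np.asarray(values, dtype=float)), "min")


class TestCDAT:
    def test_identical_stacks_give_zero(self, rng):
        vals = rng.normal(-10, 2, size=(6, 6))
        d = cdat_difference(_min_comp(vals), _min_comp(vals.copy()))
        np.testing.assert_array_equal(d.raster.values, 0.0)

    def test_arithmetic(self):
        d = cdat_difference(_min_comp(np.full((2, 2), -20.0)), _min_comp(np.full((2, 2), -10.0)))
        assert d.raster.values[0, 0] == -10.0

    def test_matches_elementwise_oracle(self, rng):
        f = rng.normal(-15, 3, size=(9, 9))
        r = rng.normal(-10, 2, size=(9, 9))
        d = cdat_difference(_min_comp(f), _min_comp(r))
        np.testing.assert_allclose(d.raster.values, f - r, atol=1e-12)

    def test_invariant_under_common_offset(self, rng):
        f = rng.normal(-15, 3, size=(5, 5))
        r = rng.normal(-10, 2, size=(5, 5))
        d0 = cdat_difference(_min_comp(f), _min_comp(r)).raster.values
        d1 = cdat_difference(_min_comp(f + 4.2), _min_comp(r + 4.2)).raster.values
        np.testing.assert_allclose(d0, d1, atol=1e-12)

    def test_mean_composite_rejected(self):
        mean = CompositeRaster(make_raster(np.zeros((2, 2))), "mean")
        with pytest.raises(ValueError):
            cdat_difference(mean, _min_comp(np.zeros((2, 2))))


class TestNDFI:
    def test_zero_when_flood_not_darker(self):
        # constant negative reference; flood >= reference so min(R∪F)=mean(R)
        ref = _stack([np.full((3, 3), -10.0), np.full((3, 3), -10.0)])
        flo = _stack([np.full((3, 3), -5.0)])
        out = ndfi(ref, flo)
        np.testing.assert_allclose(out.raster.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "min_rf,expected",
        [(-20.0, (-10 + 20) / (-10 - 20)), (-30.0, (-10 + 30) / (-10 - 30))],
    )
    def test_closed_form_cases(self, min_rf, expected):
        # mean(R) = -10; deeper flood minimum drives NDFI more negative
        ref = _stack([np.full((2, 2), -10.0)])
        flo = _stack([np.full((2, 2), min_rf)])
        out = ndfi(ref, flo)
        assert out.raster.values[0, 0] == pytest.approx(expected)
        assert expected in (-1 / 3, -0.5)

    def test_monotone_in_flood_minimum(self):
        ref = _stack([np.full((2, 2), -10.0)])
        vals = [ndfi(ref, _stack([np.full((2, 2), m)])).raster.values[0, 0]
                for m in (-12.0, -18.0, -25.0, -30.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_min_over_concatenated_stacks(self, rng):
        r1, r2 = rng.normal(-10, 1, (4, 4)), rng.normal(-10, 1, (4, 4))
        f1 = rng.normal(-14, 1, (4, 4))
        out = ndfi(_stack([r1, r2]), _stack([f1]))
        mean_r = (r1 + r2) / 2
        min_rf = np.minimum(np.minimum(r1, r2), f1)
        np.testing.assert_allclose(
            out.raster.values, (mean_r - min_rf) / (mean_r + min_rf), atol=1e-12
        )

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            ndfi(Stack([], []), Stack([], []))


class TestAdaptiveThreshold:
    def test_known_population_std(self):
        idx = ChangeIndexRaster(make_raster(np.array([[-2.0, -1.0, 0.0], [1.0, 2.0, NODATA_FLOAT]])), "CDAT")
        spec = adaptive_threshold(idx, kc=1.5, std_kind="population")
        assert spec.T == pytest.approx(-1.5 * np.sqrt(2.0))

    def test_constant_index_gives_that_constant(self):
        idx = ChangeIndexRaster(make_raster(np.full((3, 3), -4.0)), "CDAT")
        assert adaptive_threshold(idx).T == pytest.approx(-4.0)

    def test_kc_zero_gives_mean(self, rng):
        vals = rng.normal(-5, 2, size=(8, 8))
        idx = ChangeIndexRaster(make_raster(vals), "CDAT")
        assert adaptive_threshold(idx, kc=0.0).T == pytest.approx(vals.mean())

    def test_sample_std_variant(self, rng):
        vals = rng.normal(-5, 2, size=(6, 6))
        idx = ChangeIndexRaster(make_raster(vals), "CDAT")
        spec = adaptive_threshold(idx, kc=1.5, std_kind="sample")
        assert spec.T == pytest.approx(vals.mean() - 1.5 * vals.std(ddof=1))

    def test_eligibility_restricts_statistics(self, rng):
        vals = rng.normal(-5, 2, size=(6, 6))
        elig = np.zeros((6, 6), dtype=bool)
        elig[:3] = True
        idx = ChangeIndexRaster(make_raster(vals), "CDAT")
        spec = adaptive_threshold(idx, kc=1.5, eligibility=elig)
        sub = vals[:3].ravel()
        assert spec.T == pytest.approx(sub.mean() - 1.5 * sub.std())

    def test_all_nodata_rejected(self):
        idx = ChangeIndexRaster(make_raster(np.full((3, 3), NODATA_FLOAT)), "CDAT")
        with pytest.raises(ValueError):
            adaptive_threshold(idx)


class TestTerrainFilter:
    def test_flat_dem_all_eligible(self):
        dem = make_raster(np.full((10, 10), 100.0))
        assert terrain_filter(dem).all()

    def test_ramp_above_cutoff_excluded(self):
        # rise 0.1 m per 1 m -> slope atan(0.1) ≈ 5.71° > 5°
        cols = np.arange(12) * 1.0
        dem = make_raster(np.tile(cols * 0.1, (12, 1)), pixel_size=1.0)
        elig = terrain_filter(dem, 5.0)
        assert not elig[5:7, 5:7].any()

    def test_slope_matches_closed_form_on_plane(self):
        cols = np.arange(20) * 10.0
        dem = make_raster(np.tile(cols * 0.1, (20, 1)), pixel_size=10.0)
        slope = horn_slope(dem).values
        # interior pixels of a plane: slope = atan(0.1) exactly
        np.testing.assert_allclose(slope[5:-5, 5:-5], np.degrees(np.arctan(0.1)), atol=1e-9)

    def test_exact_cutoff_is_inclusive(self):
        grade = np.tan(np.radians(5.0))  # plane at exactly 5°
        cols = np.arange(20) * 10.0
        dem = make_raster(np.tile(cols * grade, (20, 1)), pixel_size=10.0)
        assert terrain_filter(dem, 5.0)[8:-8, 8:-8].all()


class TestBackgroundSeasonal:
    def test_zero_difference_excluded(self):
        d = ChangeIndexRaster(make_raster(np.array([[0.0, -5.0]])), "CDAT")
        elig = background_filter(d)
        assert not elig[0, 0] and elig[0, 1]

    def test_ndfi_input_rejected(self):
        nd = ChangeIndexRaster(make_raster(np.zeros((2, 2))), "NDFI")
        with pytest.raises(ValueError):
            background_filter(nd)

    def test_matches_elementwise_rule(self, rng):
        vals = rng.normal(0, 1, size=(7, 7))
        vals[0, :3] = 0.0
        d = ChangeIndexRaster(make_raster(vals), "CDAT")
        np.testing.assert_array_equal(background_filter(d), np.abs(vals) > 1e-6)

    @pytest.mark.parametrize("value,candidate", [(-18.9, False), (-19.1, True), (-19.0, False)])
    def test_seasonal_cutoff_strictly_below(self, value, candidate):
        comp = CompositeRaster(make_raster(np.full((2, 2), value)), "min")
        assert seasonal_filter(comp, -19.0)[0, 0] == candidate

    def test_minus_infinity_cutoff_excludes_all(self, rng):
        comp = CompositeRaster(make_raster(rng.normal(-20, 5, (5, 5))), "min")
        assert not seasonal_filter(comp, -np.inf).any()


class TestClassifyAndSynergy:
    def test_value_at_threshold_is_not_flooded(self):
        idx = ChangeIndexRaster(make_raster(np.array([[-3.242, -3.2421]])), "CDAT")
        out = classify_flood(idx, ThresholdSpec(T=-3.242))
        assert out.values[0, 0] == 0 and out.values[0, 1] == 1

    def test_calibrated_threshold_flags_below(self):
        idx = ChangeIndexRaster(make_raster(np.array([[-4.0]])), "CDAT")
        assert classify_flood(idx, ThresholdSpec(T=-3.242)).values[0, 0] == 1

    def test_matches_boolean_oracle_with_masks(self, rng):
        vals = rng.normal(-2, 3, size=(11, 11))
        m1 = rng.random((11, 11)) > 0.3
        m2 = rng.random((11, 11)) > 0.3
        idx = ChangeIndexRaster(make_raster(vals), "CDAT")
        out = classify_flood(idx, ThresholdSpec(T=-2.5), m1, m2)
        np.testing.assert_array_equal(out.values == 1, (vals < -2.5) & m1 & m2)

    def test_mask_intersection_is_order_independent(self, rng):
        vals = rng.normal(-2, 3, size=(9, 9))
        m1 = rng.random((9, 9)) > 0.4
        m2 = rng.random((9, 9)) > 0.4
        idx = ChangeIndexRaster(make_raster(vals), "CDAT")
        a = classify_flood(idx, ThresholdSpec(T=-1.0), m1, m2).values
        b = classify_flood(idx, ThresholdSpec(T=-1.0), m2, m1).values
        np.testing.assert_array_equal(a, b)

    def test_synergy_is_logical_and(self):
        a = make_binary(np.array([[1, 1], [0, 0]]))
        b = make_binary(np.array([[1, 0], [1, 0]]))
        out = synergy_map(a, b)
        np.testing.assert_array_equal(out.values, np.array([[1, 0], [0, 0]]))

    def test_synergy_area_bounded_by_each_input(self, rng):
        a = make_binary(rng.integers(0, 2, size=(20, 20)))
        b = make_binary(rng.integers(0, 2, size=(20, 20)))
        s = synergy_map(a, b)
        assert area_km2(s, 1) <= min(area_km2(a, 1), area_km2(b, 1))
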