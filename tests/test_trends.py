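"""Theil-Sen / OLS trend rasters, percentile classification, zone ratios."""

import itertools

import numpy as np
import pytest

from dhidrought.climate import classify_aridity
from dhidrought.trends import (classify_trend, ols_slope, ratio_by_zone,
                               ratio_table, theil_sen_slope)


def by_year(arr3d, years=(2017, 2018, 2019, 2020)):
    return {y: arr3d[k] for k, y in enumerate(years[:arr3d.shape[0]])}


class TestTheilSen:
    def test_exact_on_linear_series(self):
        vals = np.stack([np.full((2, 2), 1.0 + k) for k in range(4)])
        slope, ok = theil_sen_slope(by_year(vals))
        assert ok.all()
        np.testing.assert_allclose(slope, 1.0)

    def test_outlier_series_matches_pairwise_enumeration(self):
        series = [1.0, 2.0, 3.0, 100.0]
        years = [1, 2, 3, 4]
        vals = np.array(series)[:, None, None] * np.ones((4, 1, 1))
        slope, _ = theil_sen_slope({y: vals[k] for k, y in enumerate(years)})
        pairs = [(series[j] - series[i]) / (years[j] - years[i])
                 for i, j in itertools.combinations(range(4), 2)]
        assert slope[0, 0] == pytest.approx(np.median(pairs))

    def test_constant_series_zero_slope(self):
        vals = np.full((4, 3, 3), 0.7)
        slope, _ = theil_sen_slope(by_year(vals))
        np.testing.assert_allclose(slope, 0.0)

    def test_nan_years_per_pixel(self):
        vals = np.full((4, 1, 2), 1.0)
        vals[:, 0, 0] = [1.0, np.nan, 3.0, 4.0]
        vals[1:, 0, 1] = np.nan  # only one valid year
        slope, ok = theil_sen_slope(by_year(vals))
        assert ok[0, 0] and not ok[0, 1]
        pairs = [(3 - 1) / 2, (4 - 1) / 3, (4 - 3) / 1]
        assert slope[0, 0] == pytest.approx(np.median(pairs))

    def test_robust_to_single_outlier_with_five_years(self):
        years = list(range(2016, 2021))
        base = {y: np.full((1, 1), 2.0 * (y - 2016)) for y in years}
        s0, _ = theil_sen_slope(base)
        spoiled = {y: v.copy() for y, v in base.items()}
        spoiled[2018][0, 0] = 50.0
        s1, _ = theil_sen_slope(spoiled)
        assert s1[0, 0] == pytest.approx(s0[0, 0])

    def test_duplicate_years_rejected(self):
        with pytest.raises(ValueError):
            theil_sen_slope({2017: np.ones((1, 1)), 2017.0: np.ones((1, 1))})


class TestOlsSlope:
    def test_window_one_equals_closed_form(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(4, 5, 5))
        slope, _ = ols_slope(by_year(vals), spatial_window=1)
        t = np.arange(4) - 1.5
        expected = np.tensordot(t, vals - vals.mean(axis=0), axes=(0, 0)) \
            / (t ** 2).sum()
        np.testing.assert_allclose(slope, expected, rtol=1e-10)

    def test_window_irrelevant_on_spatially_constant_field(self):
        vals = np.stack([np.full((5, 5), 2.0 * k) for k in range(4)])
        s1, _ = ols_slope(by_year(vals), 1)
        s3, _ = ols_slope(by_year(vals), 3)
        np.testing.assert_allclose(s1, s3)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(4, 6, 6))
        slope, _ = ols_slope(by_year(vals), spatial_window=3)
        years = np.arange(4.0)
        t = years - years.mean()
        for i in range(6):
            for j in range(6):
                sm = []
                for k in range(4):
                    acc = []
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            # 'nearest' edge handling
                            ii = min(max(i + di, 0), 5)
                            jj = min(max(j + dj, 0), 5)
                            acc.append(vals[k, ii, jj])
                    sm.append(np.mean(acc))
                sm = np.array(sm)
                exp = (t * (sm - sm.mean())).sum() / (t ** 2).sum()
                assert slope[i, j] == pytest.approx(exp, rel=1e-9)

    def test_theil_sen_equals_ols_on_noiseless_linear(self):
        vals = np.stack([np.full((3, 3), 0.5 + 0.3 * k) for k in range(4)])
        ts, _ = theil_sen_slope(by_year(vals))
        ols, _ = ols_slope(by_year(vals), 1)
        np.testing.assert_allclose(ts, ols, rtol=1e-12)

    def test_bad_window(self):
        vals = by_year(np.zeros((4, 3, 3)))
        with pytest.raises(ValueError):
            ols_slope(vals, 2)
        with pytest.raises(ValueError):
            ols_slope(vals, 5)


class TestClassifyTrend:
    def test_slopes_1_to_100_match_sort_and_count_oracle(self):
        slopes = np.arange(1.0, 101.0).reshape(10, 10)
        tm = classify_trend(slopes, pct=20.0)
        hi = np.percentile(slopes, 80.0)
        lo = np.percentile(slopes, 20.0)
        expected_pos = int((slopes >= hi).sum())
        expected_neg = int(((slopes <= lo) & (slopes < 0)).sum())
        assert int((tm.classes == 1).sum()) == expected_pos
        assert int((tm.classes == -1).sum()) == expected_neg == 0

    def test_symmetric_slopes_balanced_classes(self):
        slopes = np.arange(-50.0, 51.0).reshape(1, 101)
        tm = classify_trend(slopes, pct=20.0)
        assert (tm.classes == 1).sum() == (tm.classes == -1).sum() > 0

    def test_sign_guard(self):
        slopes = np.arange(1.0, 26.0).reshape(5, 5)
        tm = classify_trend(slopes, pct=20.0)
        assert (tm.classes == -1).sum() == 0
        assert (tm.slope[tm.classes == 1] > 0).all()

    def test_all_equal_slopes_all_indifferent(self):
        tm = classify_trend(np.full((4, 4), 1.5))
        assert (tm.classes == 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_non_indifferent_fraction_bounded(self, seed):
        rng = np.random.default_rng(seed)
        slopes = rng.normal(size=(30, 30))
        tm = classify_trend(slopes, pct=20.0)
        frac = (tm.classes != 0).sum() / tm.valid.sum()
        assert frac <= 0.4 + 1e-9

    def test_pct_out_of_range(self):
        with pytest.raises(ValueError):
            classify_trend(np.ones((2, 2)), pct=50.0)


class TestRatios:
    def _zones(self, shape):
        vals = np.linspace(0, 40, shape[0] * shape[1]).reshape(shape)
        return classify_aridity(vals)

    def test_simple_counts(self):
        zones = self._zones((1, 20))
        slope = np.zeros((1, 20))
        classes = np.zeros((1, 20), dtype=np.int8)
        # zone 1 = first 5 cells: 2 positive, 1 negative
        classes[0, :2] = 1
        classes[0, 2] = -1
        from dhidrought.trends import TrendMap
        tm = TrendMap(slope=slope, classes=classes,
                      valid=np.ones((1, 20), bool), method="theil_sen",
                      pct=20.0)
        out = ratio_by_zone(tm, zones)
        assert out["arid"]["ratio"] == pytest.approx(2.0)
        assert out["arid"]["positive_px"] == 2

    def test_zero_negative_flagged_not_inf(self):
        zones = self._zones((1, 8))
        from dhidrought.trends import TrendMap
        classes = np.zeros((1, 8), dtype=np.int8)
        classes[0, 0] = 1
        tm = TrendMap(slope=np.zeros((1, 8)), classes=classes,
                      valid=np.ones((1, 8), bool), method="theil_sen",
                      pct=20.0)
        out = ratio_by_zone(tm, zones)
        assert out["arid"]["status"] == "undefined"
        assert np.isnan(out["arid"]["ratio"])

    def test_counts_partition_stratum(self):
        rng = np.random.default_rng(3)
        zones = self._zones((10, 10))
        slopes = rng.normal(size=(10, 10))
        tm = classify_trend(slopes, pct=20.0)
        dmg = rng.random((10, 10)) < 0.4
        table = ratio_table({"cum": tm}, zones, dmg)
        tot = table[table.stratum == "total"]
        n_classified = (tm.classes != 0).sum()
        assert (tot.positive_px.sum() + tot.negative_px.sum()) == n_classified
        assert tot.n_px.sum() == 100
        d = table[table.stratum == "damaged"].n_px.sum()
        nd = table[table.stratum == "non-damaged"].n_px.sum()
        assert d + nd == 100

    def test_misaligned_grids_rejected(self):
        zones = self._zones((2, 2))
        from dhidrought.trends import TrendMap
        tm = TrendMap(slope=np.zeros((3, 3)),
                      classes=np.zeros((3, 3), dtype=np.int8),
                      valid=np.ones((3, 3), bool), method="theil_sen",
                      pct=20.0)
        with pytest.raises(ValueError):
            ratio_by_zone(tm, zones)
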