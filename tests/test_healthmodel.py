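"""Sample assembly, thinning, collinearity filters, logistic fit diagnostics."""

import numpy as np
import pandas as pd
import pytest

from dhidrought.healthmodel import (build_sample_table, filter_correlated,
                                    filter_vif, fit_logistic,
                                    make_collinear_table, mcfadden_r2,
                                    morans_i, simulate_logistic, spatial_thin,
                                    variable_importance)


def tiny_table(n=50, seed=0, p=3):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"x{k}" for k in range(p)])
    t["label"] = rng.integers(0, 2, n)
    t["x"] = rng.uniform(0, 10000, n)
    t["y"] = rng.uniform(0, 10000, n)
    return t


class TestBuildTable:
    def _inputs(self, shape=(10, 10), bad_climate=()):
        from dhidrought.dhi import compute_dhi_multiyear
        from dhidrought.synthetic import SceneParams, generate_ndvi_stack
        p = SceneParams(n_rows=shape[0], n_cols=shape[1], seed=3)
        stacks, truth = generate_ndvi_stack(p)
        multi = compute_dhi_multiyear(stacks)
        rng = np.random.default_rng(0)
        agg = {name: rng.random(shape) for name in
               ("Prec_Cum", "Prec_Min", "Prec_Var", "Temp_Cum", "Temp_Min",
                "Temp_Var", "Sun_Cum", "Sun_Min", "Sun_Var", "Dry_Cum",
                "Dry_Min", "Dry_Var")}
        for name, ij in bad_climate:
            agg[name][ij] = np.nan
        return multi, agg, truth

    def test_fully_valid_scene_yields_all_pixels(self):
        multi, agg, truth = self._inputs()
        table, man = build_sample_table(multi, agg, truth.elevation,
                                        truth.damaged_mask)
        assert len(table) == 100
        assert man["n_samples"] == 100
        assert set(table.label.unique()) <= {0, 1}

    def test_sixteen_candidate_predictors(self):
        multi, agg, truth = self._inputs()
        table, _ = build_sample_table(multi, agg, truth.elevation,
                                      truth.damaged_mask)
        preds = [c for c in table.columns
                 if c not in ("label", "row", "col", "x", "y")]
        assert len(preds) == 16

    def test_masked_climate_pixel_dropped_and_logged(self):
        multi, agg, truth = self._inputs(bad_climate=[("Prec_Cum", (4, 7))])
        table, man = build_sample_table(multi, agg, truth.elevation,
                                        truth.damaged_mask)
        assert len(table) == 99
        assert man["dropped_invalid_Prec_Cum"] == 1


class TestSpatialThin:
    def test_zero_distance_identity(self):
        t = tiny_table()
        out = spatial_thin(t, 0.0)
        pd.testing.assert_frame_equal(out, t)

    def test_coincident_points_keep_one(self):
        t = tiny_table(n=2)
        t.loc[:, ["x", "y"]] = 100.0
        assert len(spatial_thin(t, 50.0, seed=1)) == 1

    def test_regular_grid_thinning_respects_distance(self):
        xs, ys = np.meshgrid(np.arange(10) * 300.0, np.arange(10) * 300.0)
        t = pd.DataFrame({"x": xs.ravel(), "y": ys.ravel(),
                          "label": 0})
        out = spatial_thin(t, 600.0, seed=2)
        xy = out[["x", "y"]].to_numpy()
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 600.0
        # greedy retention should stay near the optimal 25-point packing
        assert len(out) >= 20

    def test_reproducible_under_seed(self):
        t = tiny_table(n=80, seed=5)
        a = spatial_thin(t, 2000.0, seed=9)
        b = spatial_thin(t, 2000.0, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCorrelationFilter:
    def test_identical_columns_one_removed(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"a": rng.standard_normal(100)})
        t["b"] = t["a"]
        t["c"] = rng.standard_normal(100)
        t["label"] = 0
        out, log = filter_correlated(t)
        assert len(log) == 1
        assert log[0]["reason"] == "correlation"
        preds = [c for c in out.columns if c != "label"]
        assert len(preds) == 2 and "c" in preds

    def test_uncorrelated_columns_untouched(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.standard_normal((500, 4)),
                         columns=list("abcd"))
        t["label"] = 0
        out, log = filter_correlated(t)
        assert log == []
        assert out.shape[1] == 5


class TestVifFilter:
    def test_orthogonal_predictors_kept(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.standard_normal((300, 3)), columns=list("abc"))
        t["label"] = 0
        out, log = filter_vif(t)
        assert log == []

    def test_linear_combination_removed_first_matches_oracle(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.standard_normal((400, 2)), columns=["x1", "x2"])
        t["x3"] = t.x1 + t.x2 + 1e-3 * rng.standard_normal(400)
        t["label"] = 0

        def vif_oracle(df, col):
            others = [c for c in ("x1", "x2", "x3") if c != col]
            X = np.column_stack([np.ones(len(df))]
                                + [df[c] for c in others])
            beta, *_ = np.linalg.lstsq(X, df[col], rcond=None)
            resid = df[col] - X @ beta
            r2 = 1 - (resid ** 2).sum() / ((df[col] - df[col].mean()) ** 2).sum()
            return 1 / (1 - r2)

        vifs = {c: vif_oracle(t, c) for c in ("x1", "x2", "x3")}
        out, log = filter_vif(t)
        assert len(log) == 1
        assert log[0]["removed"] == max(vifs, key=vifs.get)
        assert log[0]["vif"] == pytest.approx(vifs[log[0]["removed"]],
                                              rel=1e-6)

    def test_single_predictor_retained(self):
        t = pd.DataFrame({"a": np.arange(10.0), "label": 0})
        out, log = filter_vif(t)
        assert log == [] and "a" in out.columns


def test_sixteen_predictor_construction_filters_to_seven():
    """The 16-column table with 9 redundant predictors keeps exactly 7 after
    |r| > 0.8 and VIF > 5 filtering."""
    t = make_collinear_table(n=2000, seed=0)
    preds = [c for c in t.columns if c != "label"]
    assert len(preds) == 16
    f1, log1 = filter_correlated(t)
    f2, log2 = filter_vif(f1)
    retained = [c for c in f2.columns if c != "label"]
    assert len(log1) + len(log2) == 9
    assert len(retained) == 7


class TestLogisticFit:
    def test_binary_predictor_slope_equals_log_odds_ratio(self):
        # 2x2 table: x=0 -> 30/70 damaged, x=1 -> 60/40
        rows = ([{"x": 0, "label": 1}] * 30 + [{"x": 0, "label": 0}] * 70
                + [{"x": 1, "label": 1}] * 60 + [{"x": 1, "label": 0}] * 40)
        t = pd.DataFrame(rows)
        fit = fit_logistic(t, predictors=["x"])
        log_or = np.log((60 / 40) / (30 / 70))
        assert fit.params[1] == pytest.approx(log_or, rel=1e-6)
        assert fit.params[0] == pytest.approx(np.log(30 / 70), rel=1e-6)

    def test_duplication_halves_variance_not_coefficients(self):
        t = simulate_logistic((-0.5, 1.0, -0.7), n=400, seed=4)
        fit1 = fit_logistic(t)
        fit2 = fit_logistic(pd.concat([t, t], ignore_index=True))
        np.testing.assert_allclose(fit2.params, fit1.params, rtol=1e-5)
        np.testing.assert_allclose(fit2.bse, fit1.bse / np.sqrt(2),
                                   rtol=1e-4)

    def test_intercept_only_mcfadden_zero_and_balanced_symmetry(self):
        t = pd.DataFrame({"label": [0] * 50 + [1] * 50})
        fit = fit_logistic(t, predictors=[])
        assert fit.params[0] == pytest.approx(0.0, abs=1e-8)
        assert mcfadden_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_mcfadden_invariant_to_predictor_rescaling(self):
        t = simulate_logistic((0.2, 0.8, -1.1), n=600, seed=6)
        r1 = mcfadden_r2(fit_logistic(t))
        t2 = t.copy()
        t2["x1"] = t2["x1"] * 1000 + 5
        r2 = mcfadden_r2(fit_logistic(t2))
        assert r1 == pytest.approx(r2, rel=1e-8)

    def test_separable_data_flagged_and_mcfadden_near_one(self):
        x = np.concatenate([np.linspace(-3, -1, 40), np.linspace(1, 3, 40)])
        t = pd.DataFrame({"x1": x, "label": (x > 0).astype(int)})
        fit = fit_logistic(t)
        assert fit.separation
        assert mcfadden_r2(fit) > 0.95

    def test_constant_predictor_rejected(self):
        t = pd.DataFrame({"x1": np.ones(20),
                          "label": [0, 1] * 10})
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(t)

    def test_importance_is_abs_z_and_matches_p_ordering(self):
        t = simulate_logistic((0.0, 1.5, -0.2, 0.6), n=1500, seed=7)
        fit = fit_logistic(t)
        imp = variable_importance(fit)
        assert imp.index[0] == "x1"  # dominant true effect ranks first
        np.testing.assert_allclose(np.sort(imp.to_numpy()),
                                   np.sort(np.abs(fit.zvalues[1:])))
        p_order = list(pd.Series(fit.pvalues[1:],
                                 index=fit.names).sort_values().index)
        assert list(imp.index) == p_order


class TestMoransI:
    def test_smooth_gradient_positive(self):
        xs, ys = np.meshgrid(np.arange(8.0), np.arange(8.0))
        assert morans_i(xs.ravel(), xs.ravel() * 100, ys.ravel() * 100) > 0.2

    def test_checkerboard_negative(self):
        xs, ys = np.meshgrid(np.arange(8), np.arange(8))
        v = ((xs + ys) % 2).astype(float)
        assert morans_i(v.ravel(), xs.ravel() * 100.0,
                        ys.ravel() * 100.0) < 0
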