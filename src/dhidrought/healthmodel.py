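"""Logistic health-status model with collinearity filtering.

Assembles a per-pixel sample table (DHI components, climate aggregates,
elevation, binary damage label), thins samples spatially to limit
pseudo-replication, removes strongly intercorrelated predictors
(|Pearson r| > 0.8) and high-collinearity predictors (VIF > 5), fits a
binomial logistic regression

    p(X) = exp(b0 + sum_i b_i X_i) / (1 + exp(b0 + sum_i b_i X_i)),

and reports coefficients, standard errors, z / p values, McFadden's pseudo
R^2 (1 - LL_fit / LL_null; values above 0.40 indicate a very good fit) and
|z|-based variable importance.  Predictors are standardised internally for
numerical stability; coefficients are reported on both scales.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                             PerfectSeparationWarning)

from .climate import ClimateGrid, aggregate_monthly, de_martonne
from .dhi import DHIMultiYear

__all__ = [
    "PREDICTOR_NAMES",
    "ModelFit",
    "climate_aggregate_layers",
    "build_sample_table",
    "spatial_thin",
    "filter_correlated",
    "filter_vif",
    "fit_logistic",
    "mcfadden_r2",
    "variable_importance",
    "morans_i",
    "make_collinear_table",
    "simulate_logistic",
]

# 16 candidate predictors: 3 DHI components, 4 climate variables x 3
# aggregates (cumulative / minimum / variation), elevation.
PREDICTOR_NAMES = (
    "DHI_Cum", "DHI_Min", "DHI_Var",
    "Prec_Cum", "Prec_Min", "Prec_Var",
    "Temp_Cum", "Temp_Min", "Temp_Var",
    "Sun_Cum", "Sun_Min", "Sun_Var",
    "Dry_Cum", "Dry_Min", "Dry_Var",
    "DEM",
)


@dataclasses.dataclass
class ModelFit:
    """Fitted binomial logistic model (raw-scale and standardised)."""

    names: list[str]                 # predictor names, without intercept
    params: np.ndarray               # raw scale, intercept first
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    params_std: np.ndarray           # standardised-predictor scale
    bse_std: np.ndarray
    llf: float
    llnull: float
    converged: bool
    n_obs: int
    separation: bool = False  # (quasi-)separation detected; estimates capped

    def coef_table(self) -> pd.DataFrame:
        """Raw-scale coefficient table (Estimate, Std. Error, z, Pr(>|z|))."""
        return pd.DataFrame({
            "Estimate": self.params,
            "Std. Error": self.bse,
            "z value": self.zvalues,
            "Pr(>|z|)": self.pvalues,
        }, index=["(Intercept)"] + list(self.names))


def climate_aggregate_layers(clim: ClimateGrid) -> dict[str, np.ndarray]:
    """The 12 climate aggregates (cum/min/var of P, T, S, dMI) on the
    climate grid."""
    dmi, dmi_ok, _ = de_martonne(clim.precip, clim.temp, clim.valid)
    stacks = {"Prec": (clim.precip, clim.valid), "Temp": (clim.temp, clim.valid),
              "Sun": (clim.sunshine, clim.valid), "Dry": (dmi, dmi_ok)}
    out: dict[str, np.ndarray] = {}
    for var, (stack, ok) in stacks.items():
        data = np.where(ok, stack, np.nan)
        for stat, suffix in (("cumulative", "Cum"), ("minimum", "Min"),
                             ("variation", "Var")):
            agg, agg_ok = aggregate_monthly(data, stat)
            out[f"{var}_{suffix}"] = np.where(agg_ok, agg, np.nan)
    return out


def build_sample_table(dhi: DHIMultiYear,
                       climate_aggregates: Mapping[str, np.ndarray],
                       dem: np.ndarray,
                       damaged_mask: np.ndarray,
                       forest_mask: np.ndarray | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """One row per forest pixel where every layer is valid.

    All layers must already be on the analysis grid.  Returns the table and
    a manifest of drop counts per reason.
    """
    shape = dhi.grid.shape
    if forest_mask is None:
        forest_mask = np.ones(shape, dtype=bool)
    layers = {
        "DHI_Cum": dhi.longterm_cum,
        "DHI_Min": dhi.longterm_minimum,
        "DHI_Var": dhi.longterm_var,
        **{k: np.asarray(v, dtype=float) for k, v in climate_aggregates.items()},
        "DEM": np.asarray(dem, dtype=float),
    }
    for name, layer in layers.items():
        if layer.shape != shape:
            raise ValueError(f"layer {name!r} is not on the analysis grid")
    manifest = {"n_pixels": int(np.prod(shape)),
                "dropped_outside_forest": int(np.count_nonzero(~forest_mask))}
    use = forest_mask.copy()
    for name, layer in layers.items():
        bad = use & ~np.isfinite(layer)
        manifest[f"dropped_invalid_{name}"] = int(np.count_nonzero(bad))
        use &= np.isfinite(layer)
    rows, cols = np.nonzero(use)
    if rows.size == 0:
        raise ValueError("no valid samples after masking")
    table = pd.DataFrame({name: layer[use] for name, layer in layers.items()})
    table["label"] = np.asarray(damaged_mask, dtype=bool)[use].astype(int)
    table["row"] = rows
    table["col"] = cols
    x = dhi.grid.x_origin + (cols + 0.5) * dhi.grid.x_size
    y = dhi.grid.y_origin - (rows + 0.5) * dhi.grid.y_size
    table["x"] = x
    table["y"] = y
    manifest["n_samples"] = int(len(table))
    return table, manifest


def spatial_thin(table: pd.DataFrame, min_distance_m: float,
                 seed: int = 0) -> pd.DataFrame:
    """Greedy spatial thinning: no two retained samples closer than
    ``min_distance_m``.

    Iteratively removes the most-crowded sample (most neighbours within the
    exclusion distance), breaking ties at random under ``seed``, so the
    retained count is maximal-effort.  ``min_distance_m = 0`` is the
    identity.
    """
    if min_distance_m < 0:
        raise ValueError("min_distance_m must be >= 0")
    if min_distance_m == 0 or len(table) < 2:
        return table.copy()
    rng = np.random.default_rng(seed)
    xy = table[["x", "y"]].to_numpy(dtype=float)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1)
    close = d2 < min_distance_m ** 2
    np.fill_diagonal(close, False)
    alive = np.ones(len(table), dtype=bool)
    counts = close.sum(axis=1)
    while True:
        active = counts * alive
        worst = active.max()
        if worst == 0:
            break
        cand = np.flatnonzero(alive & (counts == worst))
        drop = int(rng.choice(cand))
        alive[drop] = False
        counts[close[drop]] -= 1
        counts[drop] = 0
    return table.loc[alive].copy()


def filter_correlated(table: pd.DataFrame, r_max: float = 0.8,
                      predictors: Sequence[str] | None = None
                      ) -> tuple[pd.DataFrame, list[dict]]:
    """Iteratively drop one member of every predictor pair with
    |Pearson r| > r_max.

    The dropped member is the one with the larger mean absolute correlation
    to all remaining predictors (ties broken alphabetically), which keeps
    the procedure deterministic.  Returns the table without the dropped
    columns and a removal log.
    """
    if predictors is None:
        predictors = [c for c in table.columns
                      if c not in ("label", "row", "col", "x", "y")]
    keep = list(predictors)
    if len(keep) < 2:
        raise ValueError("need at least two predictors")
    log: list[dict] = []
    while True:
        corr = table[keep].corr(method="pearson").abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = float(corr.values.max())
        if worst <= r_max or not np.isfinite(worst):
            break
        i, j = np.unravel_index(np.nanargmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        mean_a, mean_b = corr.loc[a].mean(), corr.loc[b].mean()
        if mean_a > mean_b or (mean_a == mean_b and a < b):
            drop = a
        else:
            drop = b
        log.append({"removed": drop, "reason": "correlation",
                    "partner": b if drop == a else a, "abs_r": worst})
        keep.remove(drop)
    return table.drop(columns=[c for c in predictors if c not in keep]), log


def filter_vif(table: pd.DataFrame, vif_max: float = 5.0,
               predictors: Sequence[str] | None = None
               ) -> tuple[pd.DataFrame, list[dict]]:
    """Iteratively remove the largest-VIF predictor until all VIF <= vif_max.

    VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others (with
    intercept).  Perfect collinearity yields infinite VIF and is handled by
    removal, not by a crash.  A single predictor has VIF 1 and is retained.
    """
    if predictors is None:
        predictors = [c for c in table.columns
                      if c not in ("label", "row", "col", "x", "y")]
    keep = list(predictors)
    log: list[dict] = []
    while len(keep) >= 2:
        X = sm.add_constant(table[keep].to_numpy(dtype=float), has_constant="add")
        with np.errstate(divide="ignore", invalid="ignore"):
            vifs = np.array([variance_inflation_factor(X, k + 1)
                             for k in range(len(keep))])
        vifs = np.where(np.isfinite(vifs), vifs, np.inf)
        if np.nanmax(vifs) <= vif_max:
            break
        worst = int(np.argmax(vifs))
        log.append({"removed": keep[worst], "reason": "vif",
                    "vif": float(vifs[worst])})
        keep.pop(worst)
    return table.drop(columns=[c for c in predictors if c not in keep]), log


def fit_logistic(table: pd.DataFrame,
                 predictors: Sequence[str] | None = None,
                 label_col: str = "label") -> ModelFit:
    """Maximum-likelihood binomial logistic regression of the damage label.

    Predictors are standardised (zero mean, unit SD) before fitting;
    coefficients and standard errors are mapped back to the raw scale
    (z and p values are scale-invariant).  Perfect separation and
    non-convergence are reported, not silently ignored.
    """
    if predictors is None:
        predictors = [c for c in table.columns
                      if c not in (label_col, "row", "col", "x", "y")]
    y = table[label_col].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or classes.size < 2:
        raise ValueError("label must be binary with both classes present")
    if not predictors:
        # intercept-only model has the closed-form MLE logit(mean(y));
        # LL_fit and LL_null coincide identically
        pbar = float(y.mean())
        b0 = float(np.log(pbar / (1.0 - pbar)))
        se0 = float(1.0 / np.sqrt(y.size * pbar * (1.0 - pbar)))
        ll = float(y.size * (pbar * np.log(pbar)
                             + (1.0 - pbar) * np.log(1.0 - pbar)))
        z0 = b0 / se0
        return ModelFit(names=[], params=np.array([b0]), bse=np.array([se0]),
                        zvalues=np.array([z0]),
                        pvalues=np.array([2.0 * (1.0 - _norm_cdf(abs(z0)))]),
                        params_std=np.array([b0]), bse_std=np.array([se0]),
                        llf=ll, llnull=ll, converged=True, n_obs=int(y.size))
    X = table[list(predictors)].to_numpy(dtype=float)
    mu = X.mean(axis=0) if X.size else np.empty(0)
    sd = X.std(axis=0, ddof=0) if X.size else np.empty(0)
    if (sd == 0).any():
        const = [p for p, s in zip(predictors, sd) if s == 0]
        raise ValueError(f"constant predictor(s): {const}")
    Z = (X - mu) / sd if X.size else X
    design = sm.add_constant(Z, has_constant="add")
    model = sm.Logit(y, design)
    separation = False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(disp=False, maxiter=200)
        separation = any(issubclass(w.category, PerfectSeparationWarning)
                         for w in caught)
        converged = bool(res.mle_retvals.get("converged", False))
        llf = float(res.llf)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        # (quasi-)separation: Newton hits a singular Hessian while the
        # likelihood still has a finite optimiser path.  Report it and
        # refit by BFGS, which caps the estimates at the flat region
        # (McFadden R^2 approaches 1 in the fully separable limit).
        separation = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False, method="bfgs", maxiter=500)
        converged = bool(res.mle_retvals.get("converged", False))
        llf = float(res.llf)
    llnull = float(res.llnull)

    b_std = np.asarray(res.params)
    se_std = np.asarray(res.bse)
    slopes_raw = b_std[1:] / sd
    intercept_raw = b_std[0] - float((b_std[1:] * mu / sd).sum())
    params = np.concatenate([[intercept_raw], slopes_raw])
    # intercept SE on the raw scale via the delta method
    cov = np.asarray(res.cov_params())
    a = np.concatenate([[1.0], -mu / sd])
    se_intercept = float(np.sqrt(a @ cov @ a))
    bse = np.concatenate([[se_intercept], se_std[1:] / sd])
    z = params / bse
    pvals = np.asarray(res.pvalues).copy()
    pvals[0] = 2.0 * (1.0 - _norm_cdf(abs(z[0])))
    return ModelFit(names=list(predictors), params=params, bse=bse,
                    zvalues=z, pvalues=pvals,
                    params_std=b_std, bse_std=se_std,
                    llf=llf, llnull=llnull,
                    converged=converged, n_obs=int(y.size),
                    separation=separation)


def _norm_cdf(x: float) -> float:
    from scipy.stats import norm
    return float(norm.cdf(x))


def mcfadden_r2(fit: ModelFit) -> float:
    """McFadden's pseudo R^2 = 1 - LL_fit / LL_null."""
    if fit.llnull == 0:
        raise ValueError("null log-likelihood is zero; McFadden undefined")
    return 1.0 - fit.llf / fit.llnull


def variable_importance(fit: ModelFit) -> pd.Series:
    """Importance = |z statistic| per predictor, ranked descending.

    This is the GLM convention of the common importance tooling; by
    construction the ranking equals the ascending p-value ordering.
    """
    imp = pd.Series(np.abs(fit.zvalues[1:]), index=fit.names)
    return imp.sort_values(ascending=False)


def morans_i(values: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    """Moran's I with inverse-distance weights — a spatial-autocorrelation
    diagnostic for model residuals."""
    v = np.asarray(values, dtype=float)
    xy = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n = v.size
    if n < 3:
        raise ValueError("need at least three samples")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w[~np.isfinite(w)] = 0.0
    dev = v - v.mean()
    denom = (dev ** 2).sum()
    if denom == 0:
        raise ValueError("constant values; Moran's I undefined")
    return float((n / w.sum()) * (w * np.outer(dev, dev)).sum() / denom)


def make_collinear_table(n: int = 2000, seed: int = 0,
                         beta: Sequence[float] | None = None) -> pd.DataFrame:
    """Synthetic 16-predictor table with 9 redundant columns.

    Seven independent standard-normal drivers generate the binary label
    through the logistic model; five near-duplicates (|r| > 0.9 with a
    driver) and four two-driver linear combinations (small residual noise,
    VIF far above 5) are appended.  Correlation filtering at |r| > 0.8
    followed by VIF filtering at 5 therefore removes nine columns and
    retains seven, whichever member of each redundant pair survives.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 7))
    if beta is None:
        beta = (-0.3, 1.2, -0.8, 0.6, -0.5, 0.9, -0.4, 0.7)
    beta = np.asarray(beta, dtype=float)
    eta = beta[0] + z @ beta[1:]
    p = 1.0 / (1.0 + np.exp(-eta))
    label = (rng.random(n) < p).astype(int)

    cols = {f"driver_{k + 1}": z[:, k] for k in range(7)}
    dup_noise = 0.10
    for k in range(5):  # near-duplicates of drivers 1..5
        cols[f"dup_{k + 1}"] = z[:, k] + dup_noise * rng.standard_normal(n)
    combo_noise = 0.05
    combos = {
        "combo_12": z[:, 0] + z[:, 1],
        "combo_34": z[:, 2] - z[:, 3],
        "combo_56": z[:, 4] + z[:, 5],
        "combo_67": z[:, 5] - z[:, 6],
    }
    for name, series in combos.items():
        cols[name] = series + combo_noise * rng.standard_normal(n)
    table = pd.DataFrame(cols)
    table["label"] = label
    return table


def simulate_logistic(beta: Sequence[float], n: int, seed: int = 0
                      ) -> pd.DataFrame:
    """Draw (X, label) from the logistic model with known coefficients.

    ``beta`` is (intercept, slopes...); predictors are iid standard normal.
    """
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, beta.size - 1))
    eta = beta[0] + X @ beta[1:]
    p = 1.0 / (1.0 + np.exp(-eta))
    table = pd.DataFrame(X, columns=[f"x{k + 1}" for k in range(beta.size - 1)])
    table["label"] = (rng.random(n) < p).astype(int)
    return table
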