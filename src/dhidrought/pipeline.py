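"""End-to-end orchestration: scene -> DHI -> aridity -> trends -> stats -> model.

A single :class:`RunConfig` drives the whole workflow and every artefact is
written under one output directory together with a JSON manifest (config,
seed, library versions, drop counts, per-stage timings), so a rerun with
the same config reproduces the deterministic outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as climate_mod
from . import dhi as dhi_mod
from . import grids, healthmodel, synthetic, trends
from . import groupstats

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run (synthetic-scene inputs)."""

    scene: synthetic.SceneParams = dataclasses.field(
        default_factory=synthetic.SceneParams)
    min_valid_fraction: float = 0.75
    trend_method: str = "theil_sen"   # or "ols"
    trend_pct: float = 20.0
    ols_window: int = 3
    r_max: float = 0.8
    vif_max: float = 5.0
    thin_distance_m: float = 600.0
    out_dir: str = "run_out"
    write_rasters: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.trend_pct < 50:
            raise ValueError("trend_pct must lie in (0, 50)")
        if self.trend_method not in ("theil_sen", "ols"):
            raise ValueError("trend_method must be 'theil_sen' or 'ols'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full drought-assessment workflow on a synthetic scene.

    Returns a result dictionary with the in-memory products and writes
    rasters/tables/manifest under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.scene.seed,
        "versions": _versions(),
        "stages": {},
    }
    results: dict = {"manifest": manifest}
    timer = _StageTimer(manifest)

    with timer("synthetic_scene"):
        stacks, clim, truth = synthetic.generate_scene(config.scene)
        manifest["n_composites_per_year"] = {
            str(y): stacks[y].n_composites for y in stacks}
        manifest["n_composites_total"] = int(
            sum(s.n_composites for s in stacks.values()))
        grid = config.scene.grid()
        results.update(stacks=stacks, climate=clim, truth=truth)

    with timer("dhi"):
        multi = dhi_mod.compute_dhi_multiyear(stacks, config.min_valid_fraction)
        results["dhi"] = multi
        if config.write_rasters:
            for y, ls in multi.per_year.items():
                for comp in dhi_mod.COMPONENTS:
                    grids.write_raster(out / f"dhi_{comp}_{y}.tif",
                                       np.nan_to_num(ls.component(comp),
                                                     nan=grid.nodata),
                                       grid, valid=ls.valid)
            grids.write_raster(out / "dhi_total.tif",
                               dhi_mod.dhi_total_composite(multi), grid)
        results["dhi_correlations"] = dhi_mod.dhi_component_correlations(multi)

    with timer("climate_aridity"):
        agg_coarse = healthmodel.climate_aggregate_layers(clim)
        # align the 12 aggregates + cumulative dMI onto the analysis grid
        agg = {}
        for name, layer in agg_coarse.items():
            data, ok = grids.align_to_grid(
                np.where(np.isfinite(layer), layer, clim.grid.nodata),
                clim.grid, grid, method="bilinear")
            agg[name] = np.where(ok, data, np.nan)
        results["climate_aggregates"] = agg
        cum_dmi = agg["Dry_Cum"]
        zones = climate_mod.classify_aridity(cum_dmi, truth.forest_mask, grid)
        results["zones"] = zones
        results["altitude_regression"] = {
            "damaged": climate_mod.altitude_drought_regression(
                truth.elevation, cum_dmi, truth.damaged_mask),
            "non-damaged": climate_mod.altitude_drought_regression(
                truth.elevation, cum_dmi,
                truth.forest_mask & ~truth.damaged_mask),
        }
        if config.write_rasters:
            grids.write_raster(out / "aridity_zones.tif",
                               zones.classes.astype(float), grid,
                               valid=zones.classes > 0)
            grids.write_raster(out / "cum_dmi.tif",
                               np.nan_to_num(cum_dmi, nan=grid.nodata), grid,
                               valid=np.isfinite(cum_dmi))
        manifest["aridity_breaks"] = list(zones.breaks)

    with timer("trends"):
        trend_maps: dict[str, trends.TrendMap] = {}
        for comp in dhi_mod.COMPONENTS:
            per_year = {y: multi.per_year[y].component(comp)
                        for y in multi.years}
            if config.trend_method == "theil_sen":
                slope, valid = trends.theil_sen_slope(per_year)
            else:
                slope, valid = trends.ols_slope(per_year, config.ols_window)
            trend_maps[comp] = trends.classify_trend(
                slope, valid & truth.forest_mask, config.trend_pct,
                method=config.trend_method)
            if config.write_rasters:
                grids.write_raster(out / f"trend_slope_{comp}.tif",
                                   np.nan_to_num(slope, nan=grid.nodata),
                                   grid, valid=valid)
                grids.write_raster(out / f"trend_class_{comp}.tif",
                                   trend_maps[comp].classes.astype(float), grid)
        results["trends"] = trend_maps
        rt = trends.ratio_table(trend_maps, zones, truth.damaged_mask,
                                truth.forest_mask)
        results["ratio_table"] = rt
        rt.to_csv(out / "trend_ratios.csv", index=False)

    with timer("group_stats"):
        anova_rows, tukey_rows = [], []
        year_contrasts = {}
        for comp in dhi_mod.COMPONENTS:
            for y in multi.years:
                ls = multi.per_year[y]
                use = ls.valid & truth.forest_mask
                sample = groupstats.GroupSample(
                    values=ls.component(comp)[use],
                    labels=np.where(truth.damaged_mask[use], "damaged",
                                    "non-damaged"),
                    year=y)
                an = groupstats.anova_oneway(sample)
                gs = [sample.values[sample.labels == g]
                      for g in np.unique(sample.labels)]
                checks = groupstats.check_assumptions(an["residuals"], gs)
                tk = groupstats.tukey_contrasts(sample.values, sample.labels)
                c = tk.pair("non-damaged", "damaged")
                anova_rows.append({"component": comp, "year": y,
                                   "F": an["F"], "p": an["p"],
                                   "shapiro_p": checks["shapiro_p"],
                                   "bartlett_p": checks["bartlett_p"]})
                tukey_rows.append({"component": comp, "year": y, **c})
            dmg_by_year = {
                y: multi.per_year[y].component(comp)[
                    multi.per_year[y].valid & truth.damaged_mask]
                for y in multi.years}
            year_contrasts[comp] = groupstats.year_change_contrasts(dmg_by_year)
        results["anova_table"] = pd.DataFrame(anova_rows)
        results["tukey_table"] = pd.DataFrame(tukey_rows)
        results["year_contrasts"] = year_contrasts
        results["anova_table"].to_csv(out / "anova.csv", index=False)
        results["tukey_table"].to_csv(out / "tukey.csv", index=False)
        pd.concat({c: t.to_frame() for c, t in year_contrasts.items()},
                  names=["component"]).to_csv(out / "year_contrasts.csv")

    with timer("health_model"):
        table, tbl_manifest = healthmodel.build_sample_table(
            multi, agg, truth.elevation, truth.damaged_mask,
            truth.forest_mask)
        manifest["sample_table"] = tbl_manifest
        thinned = healthmodel.spatial_thin(table, config.thin_distance_m,
                                           seed=config.scene.seed)
        manifest["sample_table"]["n_after_thinning"] = int(len(thinned))
        filtered, corr_log = healthmodel.filter_correlated(thinned,
                                                           config.r_max)
        filtered, vif_log = healthmodel.filter_vif(filtered, config.vif_max)
        manifest["predictor_filtering"] = {
            "initial": len(healthmodel.PREDICTOR_NAMES),
            "removed_correlation": [e["removed"] for e in corr_log],
            "removed_vif": [e["removed"] for e in vif_log],
        }
        fit = healthmodel.fit_logistic(filtered)
        results["sample_table"] = table
        results["model_fit"] = fit
        results["mcfadden_r2"] = healthmodel.mcfadden_r2(fit)
        results["importance"] = healthmodel.variable_importance(fit)
        resid = filtered["label"].to_numpy() - _predict(fit, filtered)
        results["morans_i_residuals"] = healthmodel.morans_i(
            resid, filtered["x"].to_numpy(), filtered["y"].to_numpy())
        fit.coef_table().to_csv(out / "model_coefficients.csv")
        results["importance"].rename("importance").to_csv(out / "importance.csv")
        manifest["model"] = {
            "n_obs": fit.n_obs,
            "converged": fit.converged,
            "retained": fit.names,
            "mcfadden_r2": results["mcfadden_r2"],
            "morans_i_residuals": results["morans_i_residuals"],
        }
        table.to_csv(out / "sample_table.csv", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return results


def _predict(fit: healthmodel.ModelFit, table: pd.DataFrame) -> np.ndarray:
    X = table[fit.names].to_numpy(dtype=float)
    eta = np.clip(fit.params[0] + X @ fit.params[1:], -35.0, 35.0)
    return 1.0 / (1.0 + np.exp(-eta))


def _versions() -> dict:
    import scipy
    import statsmodels
    import tifffile

    from . import __version__
    return {"dhidrought": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "tifffile": tifffile.__version__}


class _StageTimer:
    def __init__(self, manifest: dict) -> None:
        self.manifest = manifest
        self.stage = None

    def __call__(self, stage: str) -> "_StageTimer":
        self.stage = stage
        return self

    def __enter__(self) -> None:
        self.t0 = time.perf_counter()

    def __exit__(self, exc_type, exc, tb) -> bool:
        dt = time.perf_counter() - self.t0
        if exc_type is not None:
            self.manifest["stages"][self.stage] = {
                "status": "failed", "seconds": round(dt, 3),
                "error": f"{exc_type.__name__}: {exc}"}
            raise RuntimeError(
                f"pipeline stage {self.stage!r} failed: {exc}") from exc
        self.manifest["stages"][self.stage] = {"status": "ok",
                                               "seconds": round(dt, 3)}
        return False
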