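"""Logistic health-status model: sample assembly, spatial thinning,
collinearity filtering (|r| > 0.8, VIF > 5), fit and importance ranking."""

import numpy as np

from dhidrought import (SceneParams, build_sample_table,
                        compute_dhi_multiyear, filter_correlated, filter_vif,
                        fit_logistic, generate_scene, mcfadden_r2,
                        spatial_thin, variable_importance)
from dhidrought.grids import align_to_grid
from dhidrought.healthmodel import climate_aggregate_layers

params = SceneParams(seed=1)
stacks, climate, truth = generate_scene(params)
multi = compute_dhi_multiyear(stacks)

agg = {}
for name, layer in climate_aggregate_layers(climate).items():
    data, ok = align_to_grid(
        np.where(np.isfinite(layer), layer, climate.grid.nodata),
        climate.grid, params.grid(), "bilinear")
    agg[name] = np.where(ok, data, np.nan)

table, manifest = build_sample_table(multi, agg, truth.elevation,
                                     truth.damaged_mask, truth.forest_mask)
print(f"candidate predictors: {sum(c not in ('label','row','col','x','y') for c in table.columns)}, "
      f"samples: {len(table)}")

thinned = spatial_thin(table, min_distance_m=600.0, seed=params.seed)
print(f"after 600 m spatial thinning: {len(thinned)}")

filtered, corr_log = filter_correlated(thinned, r_max=0.8)
filtered, vif_log = filter_vif(filtered, vif_max=5.0)
print(f"removed by |r|>0.8: {[e['removed'] for e in corr_log]}")
print(f"removed by VIF>5:  {[e['removed'] for e in vif_log]}")

fit = fit_logistic(filtered)
print(f"\nMcFadden R^2 = {mcfadden_r2(fit):.3f} "
      f"(>0.40 indicates a very good fit)")
print(fit.coef_table().round(4).to_string())
print("\nimportance (|z|):")
print(variable_importance(fit).round(2).to_string())

# After filtering, a handful of weakly collinear predictors remain; the
# fitted coefficients recover the built-in structure (drought-exposed,
# low-elevation, high-seasonality stands are the damaged ones).
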