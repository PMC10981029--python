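# dhidrought

Drought assessment for coniferous forests from dense NDVI time series,
built around the three-component **Dynamic Habitat Index (DHI)**. The
package is aimed at landscape ecologists and remote-sensing analysts who
want to quantify where and how strongly a drought event degraded forest
condition, and which environmental drivers separate damaged from
non-damaged stands.

## What it computes

For each pixel and year, from a stack of 10-day NDVI composites
*p<sub>t</sub>* (t = 1..36):

- **DHI_Cum** = Σ *p<sub>t</sub>* — annual (cumulative) productivity
- **DHI_Min** = min(*p<sub>t</sub>*) — minimum vegetative cover
- **DHI_Var** = σ(*p<sub>t</sub>*) / μ(*p<sub>t</sub>*) — seasonality
  (coefficient of variation)

Around that core the package provides:

- **Aridity zonation** from monthly climate grids via the de Martonne
  index dMI = P / (T + 10); the monthly dMI is accumulated over the study
  period and cut into four equal-width zones (arid, semi-arid, semi-humid,
  humid).
- **Multi-year trends** per pixel (Theil–Sen median-of-pairwise-slopes or
  OLS after a spatial moving-window mean), classified negative /
  indifferent / positive with a two-sided 20 % percentile threshold and a
  sign guard, and tabulated as positive-to-negative area ratios per
  aridity zone and health stratum.
- **Group statistics**: one-way ANOVA with Shapiro–Wilk / Bartlett / Q–Q
  assumption checks and Tukey–Kramer simultaneous contrasts, within years
  (damaged vs non-damaged) and between years.
- **A logistic health-status model**
  p(X) = e^(β₀+Σβᵢxᵢ) / (1+e^(β₀+Σβᵢxᵢ)) over 16 candidate predictors
  (3 DHI components, cumulative/minimum/variation of precipitation,
  temperature, sunshine and dMI, elevation), with spatial thinning,
  |r| > 0.8 correlation filtering, VIF > 5 collinearity filtering,
  McFadden's pseudo-R² and |z|-based variable importance.
- **A synthetic-scene generator** producing multi-year NDVI stacks,
  climate grids, a DEM and a damage mask with known ground truth, so every
  stage can be validated end to end.
- Multi-resolution raster alignment (GeoTIFF I/O, bilinear / nearest /
  mean-aggregate / mask-fraction resampling) onto one analysis grid.

## Worked example

`examples/02_dhi_components.py` generates a 30×30 four-year scene with a
drought in 2018 and prints the per-group DHI means:

```
2017: cum damaged=18.07 intact=19.63 | min damaged=0.237 intact=0.279 | var damaged=0.362 intact=0.333
2018: cum damaged=14.28 intact=19.64 | min damaged=0.153 intact=0.278 | var damaged=0.415 intact=0.332
2019: cum damaged=14.28 intact=19.64 | min damaged=0.155 intact=0.279 | var damaged=0.415 intact=0.332
2020: cum damaged=14.28 intact=19.62 | min damaged=0.156 intact=0.280 | var damaged=0.415 intact=0.333

Spearman correlations (cum, min, var):
[[ 1.    0.97 -0.98]
 [ 0.97  1.   -0.97]
 [-0.98 -0.97  1.  ]]
```

Damaged stands start slightly below intact ones (predisposed sites), then
lose roughly a quarter of their annual productivity and half their minimum
cover from the drought year onward while their seasonality rises — and
seasonality is anti-correlated with the other two components. The other
examples walk through zonation (`03`), trends and ratios (`04`), group
contrasts (`05`), the health model (`06`) and the full pipeline (`07`).

A thin CLI wraps the same library:

```sh
dhidrought run-all --rows 50 --cols 50 --seed 1 --out-dir run_out
```

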