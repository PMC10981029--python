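# Methods

This note documents the models, conventions and design choices behind the
package, and what its synthetic validation does and does not demonstrate.

## Dynamic Habitat Index

Each calendar year contributes 36 ten-day NDVI composites p_t per pixel.
The three components are

    DHI_Cum = sum_t p_t        (annual productivity, unitless·composites)
    DHI_Min = min_t p_t        (minimum cover, NDVI units)
    DHI_Var = sd(p_t)/mean(p_t) (seasonality; coefficient of variation)

Conventions the index itself leaves open:

- **Standard deviation** is the sample SD (n−1 denominator): a year's 36
  composites are treated as a sample of the stand's phenology, not as the
  population.
- **Gaps**: components are computed over the valid composites only, with
  DHI_Cum rescaled by n_total/n_valid so sums stay comparable across
  pixels. Pixels with a valid fraction below `min_valid_fraction`
  (default 0.75) are masked; at least two valid composites are always
  required.
- **Non-positive mean NDVI** (water, snow) makes a coefficient of
  variation meaningless, so such pixels are masked rather than returned
  as huge or negative DHI_Var.
- **The long-term layer** over several years is the element-wise
  *median* of the yearly layers, valid where at least half the years are
  valid. The median is robust to one anomalous (drought) year, which is
  precisely why it is used as the "typical condition" layer.
- **DHI_Total** maps cum→red, min→green, var→blue with a per-layer
  min–max stretch to [0, 255]: high-seasonality/low-productivity stands
  read blueish, productive stands with strong seasonality reddish purple.

A brute-force per-pixel scalar loop serves as the oracle for the
vectorised implementation in the tests (exact agreement, masked entries
included).

## De Martonne aridity and zonation

Monthly dMI = P/(T+10) with P in mm/month and T in °C. The temperature
grid used is the monthly mean of daily minima — the classical index uses
mean temperature, but the analysis follows the climate products it
consumes. Cells with T ≤ −10 °C (non-positive denominator) are masked and
counted, never returned as ±∞.

"Accumulated drought" is the sum of monthly dMI over the full study
period (an alternative — dMI of summed P and mean T — is available via
`aggregate_monthly` composition but is not the default). The accumulated
map is cut into four **equal-width** intervals between the masked min and
max; intervals are half-open ([min,b1), [b1,b2), [b2,b3), [b3,max]) with
the top class closed, so a value exactly on a break belongs to the upper
(wetter) class. Equal-width intervals on a skewed distribution give
unequal zone areas by construction; that is faithful to the method, not a
defect. Zonation is computed over the forest mask by default.

## Trends and ratios

Per DHI component, the trend over the annual layers (n = 4 years by
default) is either

- **Theil–Sen**: the median of all pairwise slopes (y_j−y_i)/(t_j−t_i)
  over the pixel's valid years (≥ 2 required); robust to a single
  anomalous year, and
- **OLS with a spatial moving window**: each annual layer is first
  smoothed with a w×w mean (default 3×3, `nearest` edge handling), then
  the closed-form OLS slope over years is taken per pixel.

Classification applies a two-sided percentile threshold (default 20 %):
pixels at or below the 20th percentile of the masked slope distribution
*and* negative are "negative"; at or above the 80th *and* positive,
"positive"; the rest "indifferent". The sign guard prevents an all-positive
slope field from producing a "negative" class. Percentiles are computed
over the forest mask, separately per component. By construction the
non-indifferent fraction is at most 40 % of valid pixels.

Ratios per aridity zone and stratum (total / damaged / non-damaged) are
positive-pixel count over negative-pixel count; a zone without negative
pixels is flagged `undefined` (never ∞), an empty stratum-zone cell
`empty`.

## Group statistics

Within each year, damaged vs non-damaged values of a component are
compared by classical one-way ANOVA; residuals feed Shapiro–Wilk (on at
most 5000 deterministically subsampled residuals, scipy's validity
limit), Bartlett across groups, and ordered quantile pairs for Q–Q plots.
No automatic pass/fail decision is taken — p-values are reported.
Pairwise contrasts use Tukey–Kramer simultaneous intervals (statsmodels),
which handle unbalanced groups; the same machinery with years as groups
yields between-year change contrasts. The sampling unit is the pixel;
pseudo-replication is addressed by the health model's spatial thinning,
not by inflating the group tests, so their p-values on full scenes are
optimistic and are used directionally.

## Health-status model

The sample table holds one row per forest pixel where every layer is
valid: 16 candidate predictors (DHI_Cum/Min/Var; cumulative, minimum and
variation of precipitation, temperature, sunshine and dMI; elevation) and
the binary damage label.

- **Spatial thinning**: greedy removal of the most-crowded sample until
  no pair is closer than `min_distance` (default 600 m = two analysis
  pixels), ties broken randomly under the run seed. Greedy removal is
  maximal-effort, not provably maximal.
- **Collinearity filtering**, in this order: (1) while any pair has
  |Pearson r| > 0.8, drop the member with the larger mean absolute
  correlation to the rest (alphabetical tie-break — deterministic);
  (2) iteratively remove the largest-VIF predictor until all
  VIF = 1/(1−R²_j) ≤ 5. Correlation-first removes the cheap
  near-duplicates before the more expensive VIF regressions run.
- **Fit**: maximum-likelihood binomial logistic regression (statsmodels
  Logit). Predictors are standardised internally; coefficients and
  standard errors are mapped back to the raw scale (delta method for the
  intercept SE), z and p values being scale-invariant. The intercept-only
  model uses its closed form, so its McFadden R² is exactly 0.
  (Quasi-)separation is detected and reported on the fit object; when
  Newton's Hessian becomes singular the model is refit by BFGS, whose
  capped estimates give McFadden R² → 1 in the separable limit.
- **McFadden R²** = 1 − LL_fit/LL_null; values above 0.40 are read as a
  very good fit. **Importance** is |z| per predictor, which by
  construction ranks identically to ascending p-values.
- **Moran's I** of the response residuals with inverse-distance weights
  is reported as a spatial-autocorrelation diagnostic alongside the fit;
  it is not used as a gate.

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes,
with known truth for every stage:

- NDVI(t) = base + amp·sin(2π(doy−phase)/365) + N(0, noise_sd), clipped
  to [−1, 1]; composites on days 5/15/25 of each month; phenological peak
  at day-of-year 196 (mid-July, typical for temperate conifers);
  base 0.55, amplitude 0.25, noise SD 0.02.
- A smooth DEM spanning 75–950 m drives the climate: precipitation rises
  and temperature falls with elevation (≈ 45 mm/month and 6 °C per km),
  plus static smooth spatial anomalies per variable so the climate
  aggregates are not pure functions of elevation. The drought year gets a
  45 % precipitation deficit, a +1.5 °C warm anomaly and 15 % more
  sunshine. Climate is generated on a 3× coarser grid to exercise the
  multi-resolution alignment. Monthly weather anomalies are spatially
  coherent (one draw per month).
- The damage mask places round(damage_fraction·n_forest) pixels with
  probability increasing in aridity (coupling 0.8 by default; 1 = the
  driest pixels, 0 = random).
- Damaged stands carry a full 10 % baseline deficit in *all* years
  (predisposed sites) and, from the drought year onward, a suppression of
  the baseline by `damage_suppression`·severity and of the amplitude by
  half that amount — the baseline collapses more than the seasonal
  signal, so seasonality (CV) rises, the drought fingerprint. Severity is
  drawn per damaged pixel from U(0, 1): an analysis pixel typically
  covers a mixture of damaged and intact finer-scale cells. An optional
  geometric `recovery_rate` lets the suppression decay after the drought.
- A smooth multiplicative site-quality field (SD 0.08) scales the
  baseline, spreading both productivity and seasonality across healthy
  stands.

What passing on these scenes shows: the arithmetic of every stage is
correct against independent oracles, the directional structure (damaged
stands lower cum/min, higher var; drier lowlands; lower
positive-to-negative ratios in damaged strata) is recovered, and the
filtering/fitting machinery behaves as specified. What it does not show:
performance under real phenology (double peaks, snow contamination,
clouds), label noise of an operational damage product, or the magnitude
of real-world effect sizes — the scene's effects are strong, so its
McFadden R² (typically 0.6–0.9, sometimes separable) sits above what
heterogeneous real data would give.

## Numerical choices and degenerate inputs

- Percentiles use numpy's default linear interpolation.
- Equal-interval zonation of a constant field raises (no interval
  width); a constant-slope field classifies as all indifferent.
- All-invalid pixels are masked, never errors; empty stacks and
  inconsistent grids raise with the offending stage/file named.
- Rasters are float32 GeoTIFFs with standard georeferencing tags and a
  GDAL nodata tag; mixed-CRS inputs are rejected rather than silently
  reprojected (reprojection is out of scope).
- Problem sizes: default scenes are 50×50 pixels × 4 years × 36
  composites, which keeps every stage well under a minute while leaving
  hundreds of samples per group in the statistics; validation
  simulations use 100 replicates at n = 2000.

## Known limitations

- `align_to_grid` assumes north-up grids in one shared CRS.
- The greedy thinning can retain slightly fewer points than the optimal
  packing.
- Group tests on un-thinned pixels ignore spatial autocorrelation (see
  above); Moran's I is reported so users can judge it.
- The OLS trend's moving window smooths across the damage boundary,
  diluting edge pixels — Theil–Sen is the default for that reason.
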