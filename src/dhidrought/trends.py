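"""Pixel-wise multi-year trends and aridity-zone trend ratios.

Trends over the annual DHI layers are estimated per pixel either with the
Theil–Sen estimator (median of all pairwise slopes — robust to outliers and
non-normality) or with OLS after a spatial moving-window mean.  Slopes are
then classed negative / indifferent / positive with a two-sided percentile
threshold on the slope distribution (default 20%, i.e. 20th/80th
percentiles) guarded by sign, and positive-to-negative area ratios are
tabulated per aridity zone and health stratum.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .climate import ZONE_NAMES, AridityZoneMap

__all__ = [
    "TrendMap",
    "theil_sen_slope",
    "ols_slope",
    "classify_trend",
    "ratio_by_zone",
    "ratio_table",
]

TREND_NEGATIVE, TREND_INDIFFERENT, TREND_POSITIVE = -1, 0, 1


@dataclasses.dataclass
class TrendMap:
    """Per-pixel slope and trend class (-1 negative, 0 indifferent, +1 positive)."""

    slope: np.ndarray
    classes: np.ndarray
    valid: np.ndarray
    method: str
    pct: float


def _stack_years(values_by_year: Mapping[int, np.ndarray]
                 ) -> tuple[np.ndarray, np.ndarray]:
    years = np.array(sorted(values_by_year), dtype=float)
    if np.unique(years).size != years.size:
        raise ValueError("duplicate year timestamps")
    data = np.stack([np.asarray(values_by_year[int(y)], dtype=float)
                     for y in years])
    return years, data


def theil_sen_slope(values_by_year: Mapping[int, np.ndarray]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Theil–Sen slope per pixel: median of all pairwise slopes
    (y_j - y_i)/(t_j - t_i), i < j, over the pixel's valid (finite) years.

    Pixels with fewer than two valid years come back NaN/invalid.
    Returns (slope raster, valid mask).
    """
    years, data = _stack_years(values_by_year)
    n = years.size
    pair_slopes = []
    for i in range(n):
        for j in range(i + 1, n):
            pair_slopes.append((data[j] - data[i]) / (years[j] - years[i]))
    pairs = np.stack(pair_slopes)  # NaN where either year invalid
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        slope = np.nanmedian(pairs, axis=0)
    n_valid_years = np.isfinite(data).sum(axis=0)
    valid = n_valid_years >= 2
    slope = np.where(valid, slope, np.nan)
    return slope, valid


def ols_slope(values_by_year: Mapping[int, np.ndarray],
              spatial_window: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope per pixel after a spatial moving-window mean per year.

    Each annual layer is first smoothed with a ``spatial_window`` x
    ``spatial_window`` mean (window 1 = no smoothing), then the closed-form
    OLS slope over years is taken per pixel.  NaN cells propagate through
    the window.
    """
    if spatial_window < 1 or spatial_window % 2 == 0:
        raise ValueError("spatial_window must be an odd integer >= 1")
    years, data = _stack_years(values_by_year)
    if spatial_window > min(data.shape[1:]):
        raise ValueError("spatial_window larger than the raster")
    if spatial_window > 1:
        sm = np.empty_like(data)
        for k in range(data.shape[0]):
            layer = data[k]
            ok = np.isfinite(layer)
            filled = np.where(ok, layer, 0.0)
            s = ndimage.uniform_filter(filled, size=spatial_window, mode="nearest")
            w = ndimage.uniform_filter(ok.astype(float), size=spatial_window,
                                       mode="nearest")
            with np.errstate(invalid="ignore", divide="ignore"):
                sm[k] = np.where(w > 0, s / w, np.nan)
        data = sm
    t = years - years.mean()
    ok = np.isfinite(data)
    valid = ok.all(axis=0)
    y = np.where(ok, data, 0.0)
    ybar = y.sum(axis=0) / data.shape[0]
    num = (t[:, None, None] * (y - ybar)).sum(axis=0)
    den = float((t ** 2).sum())
    slope = np.where(valid, num / den, np.nan)
    return slope, valid


def classify_trend(slope: np.ndarray, mask: np.ndarray | None = None,
                   pct: float = 20.0, method: str = "theil_sen") -> TrendMap:
    """Two-sided percentile classification of a slope raster.

    Pixels at or below the ``pct``-th percentile of the masked slope
    distribution *and* with negative slope are classed negative; pixels at
    or above the (100-pct)-th percentile *and* positive are classed
    positive; everything else is indifferent.  An all-equal slope field
    yields all-indifferent.
    """
    if not 0.0 < pct < 50.0:
        raise ValueError("pct must lie in (0, 50)")
    slope = np.asarray(slope, dtype=float)
    if mask is None:
        mask = np.isfinite(slope)
    valid = np.asarray(mask, dtype=bool) & np.isfinite(slope)
    classes = np.zeros(slope.shape, dtype=np.int8)
    vals = slope[valid]
    if vals.size and np.ptp(vals) > 0:
        lo = np.percentile(vals, pct)
        hi = np.percentile(vals, 100.0 - pct)
        classes[valid & (slope <= lo) & (slope < 0)] = TREND_NEGATIVE
        classes[valid & (slope >= hi) & (slope > 0)] = TREND_POSITIVE
    return TrendMap(slope=slope, classes=classes, valid=valid,
                    method=method, pct=pct)


def ratio_by_zone(trend: TrendMap, zones: AridityZoneMap,
                  stratum_mask: np.ndarray | None = None) -> dict[str, dict]:
    """Positive-to-negative pixel-count ratio per aridity zone.

    Zones with no negative pixels are flagged undefined (ratio = NaN), never
    infinity; empty zone/stratum cells are flagged missing.
    """
    if trend.classes.shape != zones.classes.shape:
        raise ValueError("trend and zone rasters are not aligned")
    use = trend.valid if stratum_mask is None else (trend.valid & stratum_mask)
    out: dict[str, dict] = {}
    for code, name in enumerate(ZONE_NAMES, start=1):
        cell = use & (zones.classes == code)
        n_pos = int(np.count_nonzero(trend.classes[cell] == TREND_POSITIVE))
        n_neg = int(np.count_nonzero(trend.classes[cell] == TREND_NEGATIVE))
        entry = {"positive_px": n_pos, "negative_px": n_neg,
                 "n_px": int(np.count_nonzero(cell))}
        if entry["n_px"] == 0:
            entry["ratio"] = np.nan
            entry["status"] = "empty"
        elif n_neg == 0:
            entry["ratio"] = np.nan
            entry["status"] = "undefined"
        else:
            entry["ratio"] = n_pos / n_neg
            entry["status"] = "ok"
        out[name] = entry
    return out


def ratio_table(trends_by_component: Mapping[str, TrendMap],
                zones: AridityZoneMap, damaged_mask: np.ndarray,
                forest_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Trend-ratio table: DHI component x {total, damaged, non-damaged} x zone."""
    damaged_mask = np.asarray(damaged_mask, dtype=bool)
    if forest_mask is None:
        forest_mask = np.ones_like(damaged_mask)
    strata = {
        "total": forest_mask,
        "damaged": forest_mask & damaged_mask,
        "non-damaged": forest_mask & ~damaged_mask,
    }
    rows = []
    for comp, trend in trends_by_component.items():
        for stratum, smask in strata.items():
            per_zone = ratio_by_zone(trend, zones, smask)
            for zone, entry in per_zone.items():
                rows.append({"component": comp, "stratum": stratum, "zone": zone,
                             **entry})
    return pd.DataFrame(rows)
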