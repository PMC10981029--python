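"""Dynamic Habitat Index components from NDVI composite stacks.

For each pixel and year the three DHI components summarise the productivity
series p_t (t = 1..n composites):

    DHI_Cum = sum(p_t)          annual (cumulative) productivity
    DHI_Min = min(p_t)          minimum vegetative cover
    DHI_Var = sd(p_t) / mean(p_t)   seasonality (coefficient of variation)

The standard deviation is the sample SD (n-1 denominator).  Pixels with too
few valid composites are masked; gappy series have DHI_Cum rescaled by
n_total/n_valid so sums stay comparable across pixels.  The long-term layer
of a multi-year set is the element-wise median over the years.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy import stats

from .grids import CompositeStack, GridSpec

__all__ = [
    "DHILayerSet",
    "DHIMultiYear",
    "compute_dhi_year",
    "compute_dhi_multiyear",
    "dhi_total_composite",
    "dhi_component_correlations",
    "COMPONENTS",
]

COMPONENTS = ("cum", "minimum", "var")


@dataclasses.dataclass
class DHILayerSet:
    """Per-year DHI component rasters with a shared validity mask."""

    year: int
    cum: np.ndarray
    minimum: np.ndarray
    var: np.ndarray
    valid: np.ndarray
    n_valid: np.ndarray
    grid: GridSpec

    def component(self, name: str) -> np.ndarray:
        if name not in COMPONENTS:
            raise KeyError(f"unknown DHI component: {name!r}")
        return getattr(self, name)


@dataclasses.dataclass
class DHIMultiYear:
    """Per-year DHI sets plus long-term (median-over-years) layers."""

    years: tuple[int, ...]
    per_year: dict[int, DHILayerSet]
    longterm_cum: np.ndarray
    longterm_minimum: np.ndarray
    longterm_var: np.ndarray
    longterm_valid: np.ndarray
    grid: GridSpec

    def longterm(self, name: str) -> np.ndarray:
        if name not in COMPONENTS:
            raise KeyError(f"unknown DHI component: {name!r}")
        return getattr(self, f"longterm_{name}")


def compute_dhi_year(stack: CompositeStack,
                     min_valid_fraction: float = 0.75) -> DHILayerSet:
    """Compute DHI_Cum / DHI_Min / DHI_Var for one calendar-year stack.

    Pixels whose valid-composite fraction falls below ``min_valid_fraction``
    are masked, as are pixels with non-positive mean NDVI (the coefficient
    of variation is only meaningful for a positive-mean productivity
    series).  DHI_Cum over gappy series is rescaled by n_total/n_valid.
    """
    if not 0.0 < min_valid_fraction <= 1.0:
        raise ValueError("min_valid_fraction must lie in (0, 1]")
    year = stack.year()
    n_total = stack.n_composites
    if n_total == 0:
        raise ValueError("empty composite stack")
    vals = np.where(stack.valid, stack.values, 0.0)
    n_valid = stack.valid.sum(axis=0)
    enough = n_valid >= np.ceil(min_valid_fraction * n_total) - 1e-9
    enough &= n_valid >= 2  # sample SD needs two points

    safe_n = np.maximum(n_valid, 1)
    total = vals.sum(axis=0)
    mean = total / safe_n
    cum = total * (n_total / safe_n)
    minimum = np.where(stack.valid, stack.values, np.inf).min(axis=0)
    sd = np.sqrt(np.where(stack.valid, (stack.values - mean) ** 2, 0.0).sum(axis=0)
                 / np.maximum(n_valid - 1, 1))
    valid = enough & (mean > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(valid, sd / np.where(mean > 0, mean, 1.0), np.nan)
    cum = np.where(valid, cum, np.nan)
    minimum = np.where(valid, minimum, np.nan)
    return DHILayerSet(year=year, cum=cum, minimum=minimum, var=var,
                       valid=valid, n_valid=n_valid, grid=stack.grid)


def compute_dhi_multiyear(stacks: Mapping[int, CompositeStack],
                          min_valid_fraction: float = 0.75) -> DHIMultiYear:
    """Per-year DHI sets plus element-wise median long-term layers.

    The long-term layer is valid only where at least half the years are
    valid; the median there is taken over the valid years.
    """
    if not stacks:
        raise ValueError("need at least one year of composites")
    years = tuple(sorted(stacks))
    grids = {id(stacks[y].grid): stacks[y].grid for y in years}
    g0 = stacks[years[0]].grid
    for y in years:
        if stacks[y].grid.shape != g0.shape:
            raise ValueError("inconsistent grids across years")
    per_year = {y: compute_dhi_year(stacks[y], min_valid_fraction) for y in years}

    def med(name: str) -> tuple[np.ndarray, np.ndarray]:
        layers = np.stack([per_year[y].component(name) for y in years])
        n_ok = np.stack([per_year[y].valid for y in years]).sum(axis=0)
        ok = n_ok >= np.ceil(len(years) / 2)
        with np.errstate(all="ignore"):
            m = np.nanmedian(layers, axis=0)
        return np.where(ok, m, np.nan), ok

    lc, vc = med("cum")
    lm, vm = med("minimum")
    lv, vv = med("var")
    return DHIMultiYear(years=years, per_year=per_year,
                        longterm_cum=lc, longterm_minimum=lm, longterm_var=lv,
                        longterm_valid=vc & vm & vv, grid=g0)


def _stretch(layer: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = np.zeros(layer.shape, dtype=np.uint8)
    vals = layer[valid]
    if vals.size == 0:
        return out
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        out[valid] = np.round((layer[valid] - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return out


def dhi_total_composite(dhi: DHILayerSet | DHIMultiYear) -> np.ndarray:
    """Merge the three components into a 3-band false-colour image.

    Cumulative productivity -> red, minimum cover -> green, seasonality ->
    blue, each min-max stretched to [0, 255] over valid pixels.  High-
    seasonality, low-productivity stands therefore read blueish; productive
    stands with strong seasonality read reddish purple.
    """
    if isinstance(dhi, DHIMultiYear):
        layers = (dhi.longterm_cum, dhi.longterm_minimum, dhi.longterm_var)
        valid = dhi.longterm_valid
    else:
        layers = (dhi.cum, dhi.minimum, dhi.var)
        valid = dhi.valid
    return np.stack([_stretch(l, valid) for l in layers])


def dhi_component_correlations(dhi_sets: Mapping[int, DHILayerSet] | DHIMultiYear,
                               mask: np.ndarray | None = None) -> np.ndarray:
    """Spearman rank-correlation matrix among the three DHI components.

    Valid masked pixels are pooled across years.  A component with zero
    rank variance yields NaN entries (flagged, never silently zero).
    """
    if isinstance(dhi_sets, DHIMultiYear):
        sets = dhi_sets.per_year
    else:
        sets = dict(dhi_sets)
    cols = {name: [] for name in COMPONENTS}
    for year in sorted(sets):
        s = sets[year]
        use = s.valid if mask is None else (s.valid & mask)
        for name in COMPONENTS:
            cols[name].append(s.component(name)[use])
    data = np.stack([np.concatenate(cols[name]) for name in COMPONENTS])
    if data.shape[1] < 3:
        raise ValueError("need at least three valid masked pixels")
    corr = np.eye(3)
    for i in range(3):
        for j in range(i + 1, 3):
            if np.ptp(data[i]) == 0 or np.ptp(data[j]) == 0:
                rho = np.nan
            else:
                rho = stats.spearmanr(data[i], data[j]).statistic
            corr[i, j] = corr[j, i] = rho
    return corr
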