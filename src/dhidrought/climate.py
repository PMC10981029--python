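"""De Martonne aridity index, climate aggregation and four-zone zonation.

The de Martonne index dMI = P / (T + 10) (P in mm/month, T in deg C) scores
how much water is available relative to evaporative demand; lower values
mean drier conditions.  Monthly dMI grids are accumulated over the study
period and the accumulated map is cut into four equal-width aridity zones
(arid, semi-arid, semi-humid, humid), which downstream modules use as
strata for trend ratios.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal

import numpy as np
from scipy import stats

from .grids import GridSpec

__all__ = [
    "ClimateGrid",
    "AridityZoneMap",
    "ZONE_NAMES",
    "de_martonne",
    "aggregate_monthly",
    "classify_aridity",
    "altitude_drought_regression",
]

ZONE_NAMES = ("arid", "semi-arid", "semi-humid", "humid")


@dataclasses.dataclass
class ClimateGrid:
    """Monthly climate stacks on one grid.

    ``precip`` (mm/month), ``temp`` (deg C, monthly mean of daily minima) and
    ``sunshine`` (h/month) are [month, row, col]; ``months`` are strictly
    increasing month-start dates.
    """

    precip: np.ndarray
    temp: np.ndarray
    sunshine: np.ndarray
    months: np.ndarray
    grid: GridSpec
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.precip = np.asarray(self.precip, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        self.sunshine = np.asarray(self.sunshine, dtype=float)
        self.months = np.asarray(self.months, dtype="datetime64[M]")
        if not (self.precip.shape == self.temp.shape == self.sunshine.shape):
            raise ValueError("climate stacks must share one shape")
        if self.precip.shape[0] != self.months.shape[0]:
            raise ValueError("one month stamp per layer required")
        if len(self.months) > 1 and not np.all(np.diff(self.months) > np.timedelta64(0, "M")):
            raise ValueError("months must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(self.precip.shape, dtype=bool)
        if (self.precip[self.valid] < 0).any():
            raise ValueError("precipitation must be non-negative")
        if (self.sunshine[self.valid] < 0).any():
            raise ValueError("sunshine duration must be non-negative")

    @property
    def n_months(self) -> int:
        return int(self.precip.shape[0])


@dataclasses.dataclass
class AridityZoneMap:
    """Four-class categorical raster cut from accumulated dMI.

    ``classes`` holds codes 1..4 (1 = arid = lowest dMI, 4 = humid); 0 marks
    cells outside the mask.  ``breaks`` are the three interior break values.
    """

    classes: np.ndarray
    breaks: tuple[float, float, float]
    vmin: float
    vmax: float
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        b = self.breaks
        if not (self.vmin < b[0] < b[1] < b[2] < self.vmax):
            raise ValueError("breaks must be strictly increasing within the value range")

    def zone_mask(self, code: int) -> np.ndarray:
        return self.classes == code


def de_martonne(precip: np.ndarray, temp: np.ndarray,
                valid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, int]:
    """Element-wise de Martonne index dMI = P / (T + 10).

    Cells with T <= -10 (non-positive denominator) are masked out and
    counted, never returned as +/-inf.  Returns (dmi, valid, n_masked_temp).
    """
    precip = np.asarray(precip, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if precip.shape != temp.shape:
        raise ValueError("precipitation and temperature grids must share a shape")
    if valid is None:
        valid = np.isfinite(precip) & np.isfinite(temp)
    denom_ok = temp > -10.0
    n_bad = int(np.count_nonzero(valid & ~denom_ok))
    if n_bad:
        warnings.warn(
            f"de_martonne: masked {n_bad} cell(s) with temperature <= -10 degC",
            RuntimeWarning, stacklevel=2,
        )
    ok = valid & denom_ok
    dmi = np.zeros_like(precip)
    np.divide(precip, temp + 10.0, out=dmi, where=ok)
    return dmi, ok, n_bad


def aggregate_monthly(stack: np.ndarray,
                      statistic: Literal["cumulative", "minimum", "variation"],
                      valid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate a [month, row, col] stack across time.

    cumulative = sum; minimum = min; variation = sample SD / mean (the same
    coefficient-of-variation convention the DHI seasonality component uses).
    Variation is masked where the temporal mean is zero.
    Returns (aggregate, valid mask).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be [month, row, col]")
    if valid is None:
        valid = np.isfinite(stack)
    n_valid = valid.sum(axis=0)
    ok = n_valid == stack.shape[0]  # aggregates need complete series
    filled = np.where(valid, stack, 0.0)
    if statistic == "cumulative":
        return np.where(ok, filled.sum(axis=0), np.nan), ok
    if statistic == "minimum":
        return np.where(ok, np.where(valid, stack, np.inf).min(axis=0), np.nan), ok
    if statistic == "variation":
        if stack.shape[0] < 2:
            raise ValueError("variation requires at least two months")
        mean = filled.sum(axis=0) / np.maximum(n_valid, 1)
        sd = np.sqrt(np.where(valid, (stack - mean) ** 2, 0.0).sum(axis=0)
                     / np.maximum(n_valid - 1, 1))
        ok = ok & (mean != 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(ok, sd / np.where(mean != 0, mean, 1.0), np.nan)
        return cv, ok
    raise ValueError(f"unknown statistic: {statistic!r}")


def classify_aridity(cum_dmi: np.ndarray, mask: np.ndarray | None = None,
                     grid: GridSpec | None = None) -> AridityZoneMap:
    """Cut accumulated dMI into four equal-width aridity zones.

    Breaks divide [min, max] of the masked values into four equal intervals;
    the lowest interval is arid, the highest humid.  Intervals are half-open
    ([min, b1), [b1, b2), [b2, b3)) with the top class closed, so a value
    exactly on a break belongs to the upper class.
    """
    cum_dmi = np.asarray(cum_dmi, dtype=float)
    if mask is None:
        mask = np.isfinite(cum_dmi)
    mask = mask & np.isfinite(cum_dmi)
    vals = cum_dmi[mask]
    if vals.size < 2 or np.unique(vals).size < 2:
        raise ValueError("need at least two distinct valid values to form intervals")
    vmin, vmax = float(vals.min()), float(vals.max())
    width = (vmax - vmin) / 4.0
    breaks = (vmin + width, vmin + 2 * width, vmin + 3 * width)
    classes = np.zeros(cum_dmi.shape, dtype=np.int8)
    # np.digitize with right=False: value == break -> upper class
    classes[mask] = np.digitize(cum_dmi[mask], breaks) + 1
    return AridityZoneMap(classes=classes, breaks=breaks, vmin=vmin, vmax=vmax,
                          grid=grid)


def altitude_drought_regression(dem: np.ndarray, cum_dmi: np.ndarray,
                                mask: np.ndarray | None = None) -> dict:
    """OLS of accumulated dMI on elevation: slope, intercept, R^2.

    Used to quantify the altitude-aridity coupling (drier lowlands, wetter
    uplands) within a health stratum.
    """
    dem = np.asarray(dem, dtype=float).ravel()
    cum = np.asarray(cum_dmi, dtype=float).ravel()
    if mask is None:
        use = np.isfinite(dem) & np.isfinite(cum)
    else:
        use = np.asarray(mask, dtype=bool).ravel() & np.isfinite(dem) & np.isfinite(cum)
    x, y = dem[use], cum[use]
    if x.size < 3:
        raise ValueError("need at least three paired samples")
    if np.ptp(x) == 0:
        raise ValueError("zero elevation variance; regression undefined")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue ** 2),
        "n": int(x.size),
    }
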