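"""Damaged vs non-damaged group comparisons.

One-way ANOVA with the classical assumption checks (Shapiro–Wilk on
residuals, Bartlett across groups, Q-Q data for plotting), Tukey–Kramer
simultaneous pairwise contrasts (within a year across health status, and
across years within a stratum), and Spearman correlations between DHI
components and climate aggregates.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupSample",
    "TukeyResult",
    "anova_oneway",
    "check_assumptions",
    "tukey_contrasts",
    "year_change_contrasts",
    "spearman_with_climate",
]


@dataclasses.dataclass
class GroupSample:
    """Component values with binary health labels for one year."""

    values: np.ndarray
    labels: np.ndarray  # strings or ints; two groups for health comparisons
    year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != self.labels.shape:
            raise ValueError("values and labels must align")
        groups, counts = np.unique(self.labels, return_counts=True)
        if groups.size < 2 or (counts == 0).any():
            raise ValueError("need at least two non-empty groups")


@dataclasses.dataclass
class TukeyResult:
    """Simultaneous pairwise mean contrasts (Tukey–Kramer)."""

    pairs: list[tuple]
    diff: np.ndarray      # mean(group2) - mean(group1)
    lower: np.ndarray
    upper: np.ndarray
    p_adj: np.ndarray
    level: float

    def significant(self) -> np.ndarray:
        return self.p_adj < (1.0 - self.level)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group1": [p[0] for p in self.pairs],
            "group2": [p[1] for p in self.pairs],
            "diff": self.diff, "lower": self.lower, "upper": self.upper,
            "p_adj": self.p_adj,
            "significant": self.significant(),
        })

    def pair(self, a, b) -> dict:
        for i, (g1, g2) in enumerate(self.pairs):
            if {g1, g2} == {a, b}:
                sign = 1.0 if (g1, g2) == (a, b) else -1.0
                # diff is g2 - g1; report as b - a
                return {"diff": sign * float(self.diff[i]),
                        "lower": float(self.lower[i]) if sign > 0 else -float(self.upper[i]),
                        "upper": float(self.upper[i]) if sign > 0 else -float(self.lower[i]),
                        "p_adj": float(self.p_adj[i])}
        raise KeyError(f"no contrast for pair ({a}, {b})")


def anova_oneway(sample: GroupSample) -> dict:
    """Classical one-way ANOVA; residuals returned for assumption checks."""
    groups = [sample.values[sample.labels == g] for g in np.unique(sample.labels)]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance in every group")
    f_stat, p_value = stats.f_oneway(*groups)
    residuals = np.concatenate([g - g.mean() for g in groups])
    return {"F": float(f_stat), "p": float(p_value), "residuals": residuals,
            "df_between": len(groups) - 1,
            "df_within": sample.values.size - len(groups)}


def check_assumptions(residuals: np.ndarray,
                      groups: Sequence[np.ndarray]) -> dict:
    """Shapiro–Wilk on residuals, Bartlett across groups, Q-Q plot data.

    No automatic decision is made; the caller (or the run manifest) records
    the p-values.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 3:
        raise ValueError("Shapiro-Wilk needs at least three residuals")
    if np.ptp(residuals) == 0:
        raise ValueError("constant residuals; assumption checks undefined")
    # Shapiro-Wilk is defined for n <= 5000 in scipy; subsample deterministically
    res = residuals
    if res.size > 5000:
        res = res[np.linspace(0, res.size - 1, 5000).astype(int)]
    shapiro_p = float(stats.shapiro(res).pvalue)
    bartlett_p = float(stats.bartlett(*groups).pvalue)
    (theo_q, ordered), (slope, intercept, _) = stats.probplot(residuals)
    return {"shapiro_p": shapiro_p, "bartlett_p": bartlett_p,
            "qq_data": {"theoretical": theo_q, "ordered": ordered,
                        "slope": float(slope), "intercept": float(intercept)}}


def tukey_contrasts(values: np.ndarray, labels: np.ndarray,
                    level: float = 0.95) -> TukeyResult:
    """Tukey–Kramer simultaneous intervals for all pairwise mean differences.

    Handles unbalanced groups; the confidence interval excludes zero exactly
    when the adjusted p-value falls below 1 - level.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two observations")
    res = pairwise_tukeyhsd(values, labels, alpha=1.0 - level)
    pairs = [
        (res.groupsunique[i], res.groupsunique[j])
        for i in range(len(res.groupsunique))
        for j in range(i + 1, len(res.groupsunique))
    ]
    return TukeyResult(pairs=pairs, diff=np.asarray(res.meandiffs, dtype=float),
                       lower=np.asarray(res.confint[:, 0], dtype=float),
                       upper=np.asarray(res.confint[:, 1], dtype=float),
                       p_adj=np.asarray(res.pvalues, dtype=float), level=level)


def year_change_contrasts(values_by_year: Mapping[int, np.ndarray],
                          level: float = 0.95) -> TukeyResult:
    """Between-year Tukey contrasts for one stratum (years act as groups)."""
    years = sorted(values_by_year)
    if len(years) < 2:
        raise ValueError("need at least two years")
    values = np.concatenate([np.asarray(values_by_year[y], dtype=float)
                             for y in years])
    labels = np.concatenate([np.full(len(values_by_year[y]), y) for y in years])
    return tukey_contrasts(values, labels, level=level)


def spearman_with_climate(dhi_components: Mapping[str, np.ndarray],
                          climate_aggregates: Mapping[str, np.ndarray],
                          mask: np.ndarray | None = None) -> pd.DataFrame:
    """Spearman rank correlation of every DHI component with every climate
    aggregate over valid masked pixels.  Constant variables are flagged NaN."""
    any_arr = next(iter(dhi_components.values()))
    if mask is None:
        mask = np.ones(np.asarray(any_arr).shape, dtype=bool)
    rows = {}
    for cname, cvals in dhi_components.items():
        cvals = np.asarray(cvals, dtype=float)
        row = {}
        for aname, avals in climate_aggregates.items():
            avals = np.asarray(avals, dtype=float)
            use = mask & np.isfinite(cvals) & np.isfinite(avals)
            x, y = cvals[use], avals[use]
            if x.size < 3:
                raise ValueError("need at least three valid pixels")
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                row[aname] = np.nan
            else:
                row[aname] = float(stats.spearmanr(x, y).statistic)
        rows[cname] = row
    return pd.DataFrame(rows).T
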