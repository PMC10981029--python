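"""Synthetic drought scenes with known ground truth.

Emulates the statistical structure of the real inputs of a drought
assessment over temperate coniferous forest: dense 10-day NDVI composites
(seasonal sinusoid plus noise, with a persistent productivity suppression of
damaged pixels from a drought year onward), spatially smooth monthly climate
grids on a coarser grid with an altitude-coupled aridity gradient, a DEM,
and a binary damage mask whose placement can be coupled to aridity.  Every
downstream stage can therefore be checked against the generating truth.

Scene realism choices (see docs/methods.md): composites fall on days 5/15/25
of each month; the phenological peak sits at day-of-year 196 (mid-July,
typical for temperate conifers); damage suppresses the NDVI baseline fully
and the seasonal amplitude only partially, so damaged stands show lower
annual productivity, lower minimum cover and *higher* seasonality — the
drought fingerprint the analysis is designed to detect.  Damaged sites carry
a small pre-drought productivity deficit (they were predisposed stands, not
random pixels).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .climate import ClimateGrid
from .grids import CompositeStack, GridSpec, align_to_grid

__all__ = [
    "SceneParams",
    "SceneTruth",
    "generate_ndvi_stack",
    "generate_climate_grids",
    "generate_damage_mask",
    "generate_scene",
]

_PEAK_DOY = 196.0  # mid-July phenological peak


@dataclasses.dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic drought scene.

    NDVI follows base + amplitude*sin(2*pi*(doy - phase)/365) + N(0, noise_sd),
    clipped to [-1, 1].  Damaged pixels have the base reduced by the full
    ``pre_drought_deficit`` in all years and, from ``drought_year`` onward,
    base reduced by ``damage_suppression`` and amplitude by
    ``damage_suppression * amplitude_suppression_ratio`` (seasonality rises
    when the evergreen baseline collapses).  ``recovery_rate`` lets the
    suppression decay geometrically in the years after the drought.

    Two heterogeneity terms keep analysis-grid pixels from being identical
    copies of one curve: a spatially smooth multiplicative site-quality
    field (SD ``site_quality_sd``) scaling the baseline (so both annual
    productivity and seasonality vary across healthy stands), and
    a per-pixel damage severity drawn uniformly from
    ``damage_severity_range`` that scales the suppression — an analysis
    pixel usually covers a mixture of damaged and intact finer-scale cells,
    so full-strength suppression everywhere would be unrealistic.  Set
    ``site_quality_sd = 0`` and ``damage_severity_range = (1, 1)`` for the
    homogeneous closed-form case.
    """

    n_rows: int = 50
    n_cols: int = 50
    years: tuple[int, ...] = (2017, 2018, 2019, 2020)
    composites_per_month: int = 3
    ndvi_base: float = 0.55
    ndvi_amplitude: float = 0.25
    noise_sd: float = 0.02
    drought_year: int = 2018
    damage_fraction: float = 0.3
    damage_suppression: float = 0.4
    amplitude_suppression_ratio: float = 0.5
    pre_drought_deficit: float = 0.10
    recovery_rate: float = 0.0
    site_quality_sd: float = 0.08
    damage_severity_range: tuple[float, float] = (0.0, 1.0)
    damage_aridity_coupling: float = 0.8
    elevation_range_m: tuple[float, float] = (75.0, 950.0)
    climate_scale: int = 3
    climate_elev_coupling: float = 1.0
    dropout_fraction: float = 0.0
    pixel_size_m: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.composites_per_month < 1:
            raise ValueError("composites_per_month must be >= 1")
        if not 0.0 <= self.damage_fraction <= 1.0:
            raise ValueError("damage_fraction must lie in [0, 1]")
        if not 0.0 <= self.damage_suppression <= 1.0:
            raise ValueError("damage_suppression must lie in [0, 1]")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1)")
        if self.elevation_range_m[0] >= self.elevation_range_m[1]:
            raise ValueError("elevation_range_m must be (min, max) with min < max")
        # noiseless signal must stay inside the NDVI range for every pixel class
        hi = self.ndvi_base + self.ndvi_amplitude
        lo = min(
            self.ndvi_base - self.ndvi_amplitude,
            self.ndvi_base * (1 - self.pre_drought_deficit) * (1 - self.damage_suppression)
            - self.ndvi_amplitude,
        )
        if hi > 1.0 or lo < -1.0:
            raise ValueError(
                "ndvi_base/ndvi_amplitude/damage settings drive the noiseless "
                "signal outside [-1, 1]"
            )

    def grid(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows, n_cols=self.n_cols,
            x_origin=500000.0, y_origin=5600000.0,
            x_size=self.pixel_size_m, y_size=self.pixel_size_m,
        )

    def climate_grid_spec(self) -> GridSpec:
        f = self.climate_scale
        return GridSpec(
            n_rows=-(-self.n_rows // f), n_cols=-(-self.n_cols // f),
            x_origin=500000.0, y_origin=5600000.0,
            x_size=self.pixel_size_m * f, y_size=self.pixel_size_m * f,
        )


@dataclasses.dataclass
class SceneTruth:
    """Ground truth of a generated scene.

    ``site_quality`` is the smooth multiplicative stand-quality field
    (mean 1); ``damage_severity`` is zero for intact pixels and the drawn
    severity for damaged ones.
    """

    params: SceneParams
    elevation: np.ndarray        # m, fine grid
    aridity: np.ndarray          # unitless in [0, 1]; higher = drier
    forest_mask: np.ndarray
    damaged_mask: np.ndarray
    site_quality: np.ndarray | None = None
    damage_severity: np.ndarray | None = None

    def _severity(self) -> np.ndarray:
        if self.damage_severity is None:
            return self.damaged_mask.astype(float)
        return self.damage_severity

    def _quality(self) -> np.ndarray:
        if self.site_quality is None:
            return np.ones(self.damaged_mask.shape)
        return self.site_quality

    def suppression_decay(self, year: int) -> float:
        p = self.params
        if year < p.drought_year:
            return 0.0
        return (1.0 - p.recovery_rate) ** (year - p.drought_year)

    def true_base(self, year: int) -> np.ndarray:
        """Per-pixel noiseless NDVI baseline in the given year.

        The pre-drought deficit applies to every damaged stand in full
        (predisposed sites were already weaker); the drought suppression is
        scaled by the pixel's damage severity.
        """
        p = self.params
        sev = self._severity()
        f = (1.0 - p.pre_drought_deficit * self.damaged_mask) \
            * (1.0 - p.damage_suppression * sev * self.suppression_decay(year))
        return p.ndvi_base * self._quality() * f

    def true_amplitude(self, year: int) -> np.ndarray:
        p = self.params
        sev = self._severity()
        s = p.damage_suppression * sev * self.suppression_decay(year) \
            * p.amplitude_suppression_ratio
        return p.ndvi_amplitude * (1.0 - s) * np.ones(sev.shape)


def _rng(params: SceneParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  sigma: float) -> np.ndarray:
    """Standardised spatially smooth Gaussian field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def _terrain(params: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    """Elevation (m, exactly spanning elevation_range_m) and aridity in [0,1]."""
    rng = _rng(params, 1)
    shape = (params.n_rows, params.n_cols)
    rows = np.linspace(0.0, 1.0, params.n_rows)[:, None] * np.ones(shape)
    relief = 0.6 * rows + 0.4 * _smooth_field(shape, rng, sigma=max(min(shape) / 8, 1))
    relief = (relief - relief.min()) / (relief.max() - relief.min() + 1e-12)
    lo, hi = params.elevation_range_m
    elevation = lo + relief * (hi - lo)
    # drier lowlands: aridity anti-correlated with altitude plus smooth noise
    arid = 0.85 * (1.0 - relief) + 0.15 * (
        0.5 + 0.5 * _smooth_field(shape, rng, sigma=max(min(shape) / 10, 1))
    )
    aridity = np.clip((arid - arid.min()) / (arid.max() - arid.min() + 1e-12), 0.0, 1.0)
    return elevation, aridity


def generate_damage_mask(truth: SceneTruth, coupling: float | None = None,
                         seed: int | None = None) -> np.ndarray:
    """Place damaged pixels among the forest, biased toward high aridity.

    With ``coupling`` = 1 the driest forest pixels are damaged; with 0 the
    placement is spatially random.  Exactly
    round(damage_fraction * n_forest_pixels) pixels are marked.
    """
    p = truth.params
    if coupling is None:
        coupling = p.damage_aridity_coupling
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng([p.seed if seed is None else seed, 2])
    forest_idx = np.flatnonzero(truth.forest_mask)
    k = int(round(p.damage_fraction * forest_idx.size))
    mask = np.zeros(truth.forest_mask.shape, dtype=bool)
    if k == 0:
        return mask
    arid = truth.aridity.ravel()[forest_idx]
    rank = stats_rank(arid)
    score = coupling * rank + (1.0 - coupling) * rng.random(forest_idx.size)
    chosen = forest_idx[np.argsort(score)[::-1][:k]]
    mask.ravel()[chosen] = True
    return mask


def stats_rank(x: np.ndarray) -> np.ndarray:
    """Normalised ranks in [0, 1] (ties broken by position, deterministic)."""
    order = np.argsort(x, kind="stable")
    rank = np.empty_like(order, dtype=float)
    rank[order] = np.arange(x.size)
    return rank / max(x.size - 1, 1)


def _composite_dates(year: int, composites_per_month: int) -> np.ndarray:
    c = composites_per_month
    offsets = np.floor((np.arange(c) + 0.5) / c * 30).astype(int)  # c=3 -> 5,15,25
    days = []
    for month in range(1, 13):
        start = np.datetime64(f"{year}-{month:02d}-01")
        for off in offsets:
            days.append(start + np.timedelta64(int(off), "D"))
    return np.array(days, dtype="datetime64[D]")


def make_truth(params: SceneParams) -> SceneTruth:
    elevation, aridity = _terrain(params)
    forest = np.ones((params.n_rows, params.n_cols), dtype=bool)
    truth = SceneTruth(params=params, elevation=elevation, aridity=aridity,
                       forest_mask=forest,
                       damaged_mask=np.zeros_like(forest))
    truth.damaged_mask = generate_damage_mask(truth)
    rng = _rng(params, 5)
    if params.site_quality_sd > 0:
        q = 1.0 + params.site_quality_sd * _smooth_field(
            forest.shape, rng, sigma=max(min(forest.shape) / 10, 1))
        truth.site_quality = np.clip(q, 0.5, 1.5)
    lo, hi = params.damage_severity_range
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError("damage_severity_range must satisfy 0 <= lo <= hi <= 1")
    sev = np.zeros(forest.shape)
    sev[truth.damaged_mask] = rng.uniform(lo, hi,
                                          size=int(truth.damaged_mask.sum()))
    truth.damage_severity = sev
    return truth


def generate_ndvi_stack(params: SceneParams,
                        truth: SceneTruth | None = None
                        ) -> tuple[dict[int, CompositeStack], SceneTruth]:
    """Generate per-year NDVI composite stacks plus the scene truth.

    Each year holds composites_per_month * 12 composites.  Non-damaged
    pixels follow the seasonal sinusoid with additive Gaussian noise; damaged
    pixels are suppressed as described on :class:`SceneParams`.  Fixed seeds
    regenerate bit-identical scenes.
    """
    if truth is None:
        truth = make_truth(params)
    rng = _rng(params, 3)
    grid = params.grid()
    stacks: dict[int, CompositeStack] = {}
    for year in params.years:
        dates = _composite_dates(year, params.composites_per_month)
        doy = (dates - dates.astype("datetime64[Y]")).astype(int) + 1
        base = truth.true_base(year)
        amp = truth.true_amplitude(year)
        season = np.sin(2.0 * np.pi * (doy[:, None, None] - (_PEAK_DOY - 365.0 / 4))
                        / 365.0)
        vals = base[None] + amp[None] * season
        if params.noise_sd > 0:
            vals = vals + rng.normal(0.0, params.noise_sd, size=vals.shape)
        vals = np.clip(vals, -1.0, 1.0)
        valid = np.ones(vals.shape, dtype=bool)
        if params.dropout_fraction > 0:
            valid &= rng.random(vals.shape) >= params.dropout_fraction
        stacks[year] = CompositeStack(values=vals, valid=valid, dates=dates, grid=grid)
    return stacks, truth


def generate_climate_grids(params: SceneParams,
                           truth: SceneTruth | None = None) -> ClimateGrid:
    """Monthly precipitation, temperature and sunshine grids.

    Generated on a grid ``climate_scale`` times coarser than the NDVI grid
    (mirroring the 300 m vs 1000 m product mismatch).  Precipitation rises
    and temperature falls with elevation (lapse), so aridity is
    anti-correlated with altitude; the drought year gets a pronounced
    precipitation deficit and warm anomaly.  Weather noise is shared across
    space within a month (regionally coherent anomalies).
    """
    if truth is None:
        truth = make_truth(params)
    rng = _rng(params, 4)
    cgrid = params.climate_grid_spec()
    elev_c, _ = align_to_grid(truth.elevation, params.grid(), cgrid,
                              method="mean_aggregate")
    elev_km = elev_c / 1000.0
    c = params.climate_elev_coupling
    months = np.arange(
        np.datetime64(f"{min(params.years)}-01"),
        np.datetime64(f"{max(params.years) + 1}-01"),
    )
    month_no = (months.astype(int) % 12) + 1  # 1..12
    yr = months.astype("datetime64[Y]").astype(int) + 1970
    phase = np.cos(2.0 * np.pi * (month_no - 7) / 12.0)  # 1 in July
    drought = yr == params.drought_year

    p_anom = rng.normal(0.0, 6.0, size=months.size)
    t_anom = rng.normal(0.0, 0.6, size=months.size)
    s_anom = rng.normal(0.0, 12.0, size=months.size)
    # static smooth spatial anomalies (rain shadows, local exposure) keep the
    # three variables from being pure functions of elevation
    sig = max(min(cgrid.shape) / 6, 1)
    p_spat = c * 8.0 * _smooth_field(cgrid.shape, rng, sig)
    t_spat = c * 0.5 * _smooth_field(cgrid.shape, rng, sig)
    s_spat = c * 10.0 * _smooth_field(cgrid.shape, rng, sig)

    precip = (55.0 + 12.0 * phase + p_anom)[:, None, None] \
        + (c * 45.0 * elev_km + p_spat)[None]
    precip = precip * np.where(drought, 0.55, 1.0)[:, None, None]
    precip = np.clip(precip, 0.0, None)

    temp = (5.5 + 6.5 * phase + t_anom)[:, None, None] \
        - (c * 6.0 * elev_km - t_spat)[None]
    temp = temp + np.where(drought, 1.5, 0.0)[:, None, None]

    sunshine = (150.0 + 95.0 * phase + s_anom)[:, None, None] \
        - (c * 15.0 * elev_km - s_spat)[None]
    sunshine = sunshine * np.where(drought, 1.15, 1.0)[:, None, None]
    sunshine = np.clip(sunshine, 0.0, None)

    return ClimateGrid(precip=precip, temp=temp, sunshine=sunshine,
                       months=months, grid=cgrid)


def generate_scene(params: SceneParams
                   ) -> tuple[dict[int, CompositeStack], ClimateGrid, SceneTruth]:
    """Full scene: NDVI stacks, climate grids and truth, one consistent seed."""
    truth = make_truth(params)
    stacks, _ = generate_ndvi_stack(params, truth)
    clim = generate_climate_grids(params, truth)
    return stacks, clim, truth
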