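"""Desk-scale synthetic world: observations, hindcasts, projections, surveys.

Real inputs to the pipeline — multi-decade SST / sub-surface salinity
reanalyses, five initialized decadal-prediction archives, CMIP6 projections
and a spawning-stock survey — are hundreds of gigabytes.  This module
generates statistically analogous stand-ins small enough to run in a test
suite, with the structural features the analysis depends on:

* a *truth* per cell of the form
  ``climatology + trend + AR(1) low-frequency signal + white noise``, with
  smooth large-scale spatial patterns so that isotherm/isohaline geometry is
  analytically tractable;
* sub-surface salinity delivered on depth layers spanning 250-600 m so the
  thickness-weighted depth average is exercised;
* initialized hindcast ensembles (model x start-year x member x lead) with
  an imposed lead- and model-dependent additive bias (forecast drift) and a
  lead-dependent predictable fraction rho(lead): members track the truth's
  low-frequency phase with weight rho and an independent surrogate with
  weight (1 - rho), plus member noise;
* uninitialized projections that share the forced trend but run on their own
  low-frequency phase (one realisation per model, lead-independent bias);
* a survey abundance field: a probability surface thinned by effort and
  lognormal observation noise onto a coarse 2 x 1 degree grid.

Everything is deterministic under ``SyntheticConfig.seed``; independent
sub-streams are spawned per stage so stages can be regenerated separately.
Defaults are a 40 x 60 half-degree North Atlantic-like box, 1960-2018,
5 models x 3 members, leads 1-10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .climatology_bias import ForecastSet
from .grids import GridError, GridField, GridSpec, LayeredField, RegionPolygon, cell_areas

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticHindcasts",
    "SyntheticSurvey",
    "simulate_truth",
    "simulate_hindcasts",
    "simulate_survey",
    "default_region",
]

#: Depth-layer interfaces (m) used for the layered salinity truth.
DEPTH_INTERFACES = (150.0, 250.0, 350.0, 450.0, 600.0, 800.0)


@dataclass
class SyntheticConfig:
    """Stated world for the synthetic experiments.

    The truth model for each variable is
    ``clim(x) + slope * (year - mid) / 10 * pattern(x) + lf(year) * pattern(x)
    + N(0, white_sd)`` with ``lf`` an AR(1) (coefficient ``phi``, innovation
    sd ``ar1_sd``).  Hindcast members blend the truth's low-frequency phase
    (weight ``rho(lead)``) with an independent surrogate AR(1) of the same
    parameters (weight ``1 - rho``).
    """

    # domain
    lat_min: float = 45.0
    lat_max: float = 65.0
    lon_min: float = -30.0
    lon_max: float = 0.0
    step: float = 0.5
    years: tuple[int, int] = (1960, 2018)
    months: tuple[int, int] = (3, 8)  # (salinity month, sst month)

    # truth: August SST (degC); meridional gradient spans both isotherms
    sst_base: float = 12.5
    sst_lat_gradient: float = -0.35  # degC per degree latitude northwards
    sst_trend: float = 0.25  # degC per decade
    sst_ar1_sd: float = 0.35  # innovation sd of the low-frequency component
    sst_white_sd: float = 0.30

    # truth: March 250-600 m salinity (psu); zonal gradient spans the window
    sal_base: float = 35.52
    sal_lon_gradient: float = -0.010  # psu per degree longitude eastwards
    sal_trend: float = -0.008  # psu per decade
    sal_ar1_sd: float = 0.030
    sal_white_sd: float = 0.012

    phi: float = 0.8  # AR(1) coefficient of the low-frequency component

    # ensemble
    n_models: int = 5
    members_per_model: int = 3
    leads: tuple[int, ...] = tuple(range(1, 11))
    bias_scale_sst: float = 0.5  # scale of imposed model/drift biases, degC
    bias_scale_sal: float = 0.05
    member_noise_sst: float = 0.30
    member_noise_sal: float = 0.015
    rho0: float = 0.9  # predictable fraction at lead 1
    rho_decay: float = 0.93  # per-lead geometric decay of rho

    # survey
    survey_effort: float = 1000.0
    survey_lognormal_sd: float = 0.3

    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.phi < 1.0:
            raise GridError("phi must be in (-1, 1)")
        for sd in (self.sst_ar1_sd, self.sst_white_sd, self.sal_ar1_sd,
                   self.sal_white_sd, self.member_noise_sst, self.member_noise_sal):
            if sd < 0:
                raise GridError("noise standard deviations must be >= 0")
        rho = self.rho(np.asarray(self.leads))
        if np.any(rho < 0) or np.any(rho > 1) or np.any(np.diff(rho) > 1e-12):
            raise GridError("rho(lead) must lie in [0, 1] and be non-increasing")

    def rho(self, lead) -> np.ndarray:
        """Predictable fraction at each lead (non-increasing, in [0, 1])."""
        return np.clip(self.rho0 * self.rho_decay ** (np.asarray(lead, dtype=float) - 1.0),
                       0.0, 1.0)

    @property
    def grid(self) -> GridSpec:
        return GridSpec.regular(self.lat_min, self.lat_max, self.lon_min, self.lon_max,
                                self.step)

    @property
    def year_list(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    @property
    def mid_year(self) -> float:
        return 0.5 * (self.years[0] + self.years[1])


@dataclass
class SyntheticTruth:
    """Observation-like fields plus the generative components (for oracles)."""

    cfg: SyntheticConfig
    grid: GridSpec
    years: np.ndarray
    sst: dict[int, GridField]
    salinity: dict[int, GridField]  # 250-600 m depth mean, March
    salinity_layered: dict[int, LayeredField]
    bathymetry: np.ndarray  # metres, positive down
    lf: dict[str, dict[int, float]]  # low-frequency series per variable, extended years
    pattern: np.ndarray  # spatial loading of trend + low-frequency signal


@dataclass
class SyntheticHindcasts:
    """Initialized ensembles and uninitialized projections for both variables."""

    sst_sets: list[ForecastSet]
    salinity_sets: list[ForecastSet]
    uninitialized_sst: dict[str, dict[int, GridField]]
    uninitialized_salinity: dict[str, dict[int, GridField]]
    bias: dict[str, np.ndarray]  # variable -> (n_models, n_leads) imposed bias
    surrogate_lf: dict[str, np.ndarray]  # variable -> (n_models, n_members, n_ext_years)


@dataclass
class SyntheticSurvey:
    """Coarse-grid abundance per year, with the grid's cell areas."""

    grid: GridSpec
    abundance: dict[int, np.ndarray]
    areas: np.ndarray


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path of length n."""
    x = np.empty(n)
    if sd == 0:
        x[:] = 0.0
        return x
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
    eps = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def _pattern(grid: GridSpec) -> np.ndarray:
    """Smooth order-one harmonic loading, mean close to 1."""
    lat = grid.lat_centers[:, None]
    lon = grid.lon_centers[None, :]
    lat_span = max(lat.max() - lat.min(), 1e-9)
    lon_span = max(lon.max() - lon.min(), 1e-9)
    return 1.0 + 0.25 * np.sin(np.pi * (lat - lat.min()) / lat_span) * np.cos(
        np.pi * (lon - lon.min()) / lon_span
    )


def _bathymetry(grid: GridSpec) -> np.ndarray:
    """Deep basin shoaling to a < 500 m shelf along the eastern edge."""
    lon = grid.lon_centers[None, :]
    lon_span = max(lon.max() - lon.min(), 1e-9)
    frac = (lon - lon.min()) / lon_span
    depth = 3000.0 - 2800.0 * frac**3
    return np.broadcast_to(depth, grid.shape).copy()


def _extended_years(cfg: SyntheticConfig) -> np.ndarray:
    return np.arange(cfg.years[0], cfg.years[1] + max(cfg.leads) + 1)


def _truth_components(cfg: SyntheticConfig, var: str):
    if var == "sst":
        base = cfg.sst_base + cfg.sst_lat_gradient * (
            cfg.grid.lat_centers[:, None] - cfg.lat_min
        ) * np.ones((1, cfg.grid.lon_centers.size))
        return base, cfg.sst_trend, cfg.sst_ar1_sd, cfg.sst_white_sd
    base = cfg.sal_base + cfg.sal_lon_gradient * (
        cfg.grid.lon_centers[None, :] - cfg.lon_min
    ) * np.ones((cfg.grid.lat_centers.size, 1))
    return base, cfg.sal_trend, cfg.sal_ar1_sd, cfg.sal_white_sd


def simulate_truth(cfg: SyntheticConfig) -> SyntheticTruth:
    """Generate the observation-like world: August SST and March salinity
    (layered + 250-600 m mean) per year, deterministic under ``cfg.seed``."""
    rng = np.random.default_rng([cfg.seed, 1])
    grid = cfg.grid
    pattern = _pattern(grid)
    ext_years = _extended_years(cfg)
    obs_years = cfg.year_list
    sal_month, sst_month = cfg.months

    out_fields: dict[str, dict[int, GridField]] = {}
    lf_series: dict[str, dict[int, float]] = {}
    for var in ("sst", "salinity"):
        base, trend, ar1_sd, white_sd = _truth_components(cfg, var)
        lf = _ar1(rng, ext_years.size, cfg.phi, ar1_sd)
        lf_series[var] = dict(zip(ext_years.tolist(), lf.tolist()))
        month = sst_month if var == "sst" else sal_month
        fields: dict[int, GridField] = {}
        for i, y in enumerate(obs_years):
            signal = base + (trend * (y - cfg.mid_year) / 10.0 + lf[i]) * pattern
            noise = rng.normal(0.0, white_sd, size=grid.shape) if white_sd > 0 else 0.0
            fields[int(y)] = GridField(grid, var, signal + noise, time=(int(y), month))
        out_fields[var] = fields

    # layered salinity whose clipped-thickness 250-600 m mean is the 2-D truth
    interfaces = np.asarray(DEPTH_INTERFACES)
    mids = 0.5 * (interfaces[:-1] + interfaces[1:])
    offsets = 0.0005 * (mids - mids.mean())  # weak vertical gradient, psu
    top, bot = interfaces[:-1], interfaces[1:]
    w = np.clip(np.minimum(bot, 600.0) - np.maximum(top, 250.0), 0.0, None)
    offsets = offsets - (offsets * w).sum() / w.sum()  # zero weighted mean
    layered: dict[int, LayeredField] = {}
    for y, f2d in out_fields["salinity"].items():
        vals = f2d.values[None, :, :] + offsets[:, None, None]
        layered[y] = LayeredField(grid, "salinity", interfaces, vals, time=f2d.time)

    return SyntheticTruth(
        cfg=cfg,
        grid=grid,
        years=obs_years,
        sst=out_fields["sst"],
        salinity=out_fields["salinity"],
        salinity_layered=layered,
        bathymetry=_bathymetry(grid),
        lf=lf_series,
        pattern=pattern,
    )


def simulate_hindcasts(truth: SyntheticTruth, cfg: SyntheticConfig | None = None
                       ) -> SyntheticHindcasts:
    """Initialized hindcast ensembles plus uninitialized projections.

    ``member(model, start, lead) = truth_deterministic(verif) + b(model, lead)
    + [rho * lf_truth(verif) + (1 - rho) * lf_surrogate(model, member, verif)]
    * pattern + member noise``; uninitialized runs share the trend but carry
    their own AR(1) phase and a lead-independent bias.
    """
    cfg = cfg or truth.cfg
    rng = np.random.default_rng([cfg.seed, 2])
    grid = truth.grid
    pattern = truth.pattern
    ext_years = _extended_years(cfg)
    starts = cfg.year_list
    leads = np.asarray(cfg.leads)
    rho = cfg.rho(leads)
    n_mod, n_mem = cfg.n_models, cfg.members_per_model
    model_ids = [f"model{m + 1:02d}" for m in range(n_mod)]
    sal_month, sst_month = cfg.months

    sets: dict[str, list[ForecastSet]] = {"sst": [], "salinity": []}
    uninit: dict[str, dict[str, dict[int, GridField]]] = {"sst": {}, "salinity": {}}
    bias: dict[str, np.ndarray] = {}
    surrogates: dict[str, np.ndarray] = {}

    for var in ("sst", "salinity"):
        base, trend, ar1_sd, white_sd = _truth_components(cfg, var)
        bscale = cfg.bias_scale_sst if var == "sst" else cfg.bias_scale_sal
        mnoise = cfg.member_noise_sst if var == "sst" else cfg.member_noise_sal
        month = sst_month if var == "sst" else sal_month
        lf = np.array([truth.lf[var][int(y)] for y in ext_years])

        # imposed model bias: constant offset + linear drift with lead
        b0 = rng.normal(0.0, bscale, size=n_mod)
        bdrift = rng.normal(0.0, bscale, size=n_mod)
        b = b0[:, None] + bdrift[:, None] * (leads[None, :] / leads.max())
        bias[var] = b

        surr = np.empty((n_mod, n_mem, ext_years.size))
        for im in range(n_mod):
            for km in range(n_mem):
                surr[im, km] = _ar1(rng, ext_years.size, cfg.phi, ar1_sd)
        surrogates[var] = surr

        verif = starts[:, None] + leads[None, :] - 1  # (n_start, n_lead)
        vidx = np.searchsorted(ext_years, verif)
        lf_v = lf[vidx]  # (n_start, n_lead)
        trend_v = trend * (verif - cfg.mid_year) / 10.0

        for im, mid in enumerate(model_ids):
            vals = np.empty((starts.size, n_mem, leads.size) + grid.shape)
            for km in range(n_mem):
                lf_mix = rho[None, :] * lf_v + (1.0 - rho[None, :]) * surr[im, km][vidx]
                det = (trend_v + lf_mix)[:, :, None, None] * pattern[None, None] \
                    + base[None, None] + b[im][None, :, None, None]
                noise = rng.normal(0.0, mnoise, size=det.shape) if mnoise > 0 else 0.0
                vals[:, km] = det + noise
            sets[var].append(
                ForecastSet(mid, grid, var, month, starts, leads, n_mem, vals)
            )

        # uninitialized: one realisation per model, own AR(1) phase
        for im, mid in enumerate(model_ids):
            b_u = rng.normal(0.0, bscale)
            own_lf = _ar1(rng, ext_years.size, cfg.phi, ar1_sd)
            fields: dict[int, GridField] = {}
            for i, y in enumerate(cfg.year_list):
                j = int(np.searchsorted(ext_years, y))
                signal = base + b_u + (trend * (y - cfg.mid_year) / 10.0 + own_lf[j]) * pattern
                noise = rng.normal(0.0, white_sd, size=grid.shape) if white_sd > 0 else 0.0
                fields[int(y)] = GridField(grid, var, signal + noise, time=(int(y), month))
            uninit[var][mid] = fields

    logger.info(
        "simulated hindcasts: %d models x %d members x %d starts x %d leads",
        n_mod, n_mem, starts.size, leads.size,
    )
    return SyntheticHindcasts(
        sst_sets=sets["sst"],
        salinity_sets=sets["salinity"],
        uninitialized_sst=uninit["sst"],
        uninitialized_salinity=uninit["salinity"],
        bias=bias,
        surrogate_lf=surrogates,
    )


def coarse_survey_grid(cfg: SyntheticConfig) -> GridSpec:
    """The 2-degree-lon x 1-degree-lat survey grid covering the domain."""
    lats = np.arange(cfg.lat_min + 0.5, cfg.lat_max, 1.0)
    lons = np.arange(cfg.lon_min + 1.0, cfg.lon_max, 2.0)
    return GridSpec(lats, lons)


def simulate_survey(
    prob_fields: Mapping[int, GridField],
    cfg: SyntheticConfig,
) -> SyntheticSurvey:
    """Survey abundance: effort x mean probability x lognormal noise on the
    coarse 2 x 1 degree grid, deterministic under ``cfg.seed``."""
    rng = np.random.default_rng([cfg.seed, 3])
    years = sorted(prob_fields)
    fine = prob_fields[years[0]].grid
    coarse = coarse_survey_grid(cfg)
    # map each fine cell to its coarse cell (centre containment)
    li = np.clip(np.searchsorted(coarse.lat_centers - 0.5, fine.lat_centers, side="right") - 1,
                 0, coarse.lat_centers.size - 1)
    lj = np.clip(np.searchsorted(coarse.lon_centers - 1.0, fine.lon_centers, side="right") - 1,
                 0, coarse.lon_centers.size - 1)
    LI, LJ = np.meshgrid(li, lj, indexing="ij")
    abundance: dict[int, np.ndarray] = {}
    for y in years:
        p = prob_fields[y].masked_values()
        sums = np.zeros(coarse.shape)
        counts = np.zeros(coarse.shape)
        ok = np.isfinite(p)
        np.add.at(sums, (LI[ok], LJ[ok]), p[ok])
        np.add.at(counts, (LI[ok], LJ[ok]), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_p = np.where(counts > 0, sums / counts, 0.0)
        if cfg.survey_lognormal_sd > 0:
            noise = rng.lognormal(0.0, cfg.survey_lognormal_sd, size=coarse.shape)
        else:
            noise = 1.0
        abundance[int(y)] = cfg.survey_effort * mean_p * noise
    return SyntheticSurvey(coarse, abundance, cell_areas(coarse))


def default_region(cfg: SyntheticConfig, name: str = "study-region",
                   inset: float = 2.0) -> RegionPolygon:
    """Rectangular study region inset from the domain edges."""
    return RegionPolygon.from_vertices(
        name,
        [
            (cfg.lon_min + inset, cfg.lat_min + inset),
            (cfg.lon_max - inset, cfg.lat_min + inset),
            (cfg.lon_max - inset, cfg.lat_max - inset),
            (cfg.lon_min + inset, cfg.lat_max - inset),
            (cfg.lon_min + inset, cfg.lat_min + inset),
        ],
    )
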