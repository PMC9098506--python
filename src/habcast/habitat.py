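"""Species habitat models and habitat-area metrics.

Three North Atlantic case studies motivate the model forms:

* **Mackerel** — distribution is cold-limited at the surface; suitable
  habitat is where mean August SST >= 8.5 degC (the Greenland EEZ south of
  70 N is the region of interest).
* **Bluefin tuna** — needs access to surface waters warm enough to support
  foraging; suitable where mean August SST >= 11 degC.
* **Blue whiting** — spawning habitat west of Great Britain and Ireland is
  set by sub-surface (250-600 m mean) March salinity.  Larval occurrence has
  a dome-shaped response to salinity, essentially confined to 35.3-35.5 psu;
  the published probability model (latitude, day of year, bathymetry, solar
  elevation angle, salinity) is represented here by a pluggable interface
  with a documented simplified default, and the binary salinity window is the
  science-anchored fallback.

Probability models require calibration before their output can be compared
with *adult distribution* areas from surveys: the probability cutoff is
chosen so that the upper quartile (Q3) of the annual habitat areas matches
the Q3 of the observed annual distribution areas.

All threshold comparisons are boundary-inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .grids import GridError, GridField, RegionPolygon, cell_areas, region_mask

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdHabitatModel",
    "SalinityWindowHabitatModel",
    "HabitatSeries",
    "threshold_suitability",
    "salinity_window_suitability",
    "larvae_probability",
    "register_probability_model",
    "default_dome_probability",
    "solar_elevation",
    "habitat_area",
    "probability_area_curve",
    "calibrate_probability_threshold",
    "core_distribution_area",
    "MACKEREL",
    "BLUEFIN_TUNA",
    "BLUE_WHITING",
]


@dataclass(frozen=True)
class ThresholdHabitatModel:
    """Cold-limit isotherm habitat model: suitable where value >= threshold."""

    species: str
    threshold: float
    variable: str = "sst"
    month: int = 8

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise GridError("threshold must be finite")
        if not 1 <= self.month <= 12:
            raise GridError("month must be in 1..12")


@dataclass(frozen=True)
class SalinityWindowHabitatModel:
    """Spawning-habitat model on the 250-600 m March salinity mean.

    ``window`` is a closed salinity interval in psu.  ``probability_model``
    optionally names a registered probability function of
    (lat, day_of_year, bathymetry, salinity, solar_elevation); its output is
    thresholded at ``calibration_threshold`` to give binary habitat.
    """

    species: str = "blue whiting"
    window: tuple[float, float] = (35.3, 35.5)
    variable: str = "salinity"
    month: int = 3
    probability_model: str | None = None
    calibration_threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.window[0] < self.window[1]:
            raise GridError(f"salinity window must have lower < upper, got {self.window}")


# Study defaults for the three species.
MACKEREL = ThresholdHabitatModel("mackerel", threshold=8.5)
BLUEFIN_TUNA = ThresholdHabitatModel("bluefin tuna", threshold=11.0)
BLUE_WHITING = SalinityWindowHabitatModel()


@dataclass
class HabitatSeries:
    """Annual suitable-habitat area (km²) in a named region for one source."""

    species: str
    region: str
    source: str  # obs | <model_id> | grand_ensemble | member:k | persistence | binned-w | uninitialized
    years: np.ndarray
    areas: np.ndarray
    lead_years: int | None = None
    model_id: str | None = None
    member: int | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.years.shape != self.areas.shape:
            raise GridError("years and areas must have equal length")
        if self.years.size > 1 and np.any(np.diff(self.years) <= 0):
            raise GridError("years must be strictly increasing")
        if np.any(self.areas[np.isfinite(self.areas)] < 0):
            raise GridError("areas must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-year representation."""
        return pd.DataFrame(
            {
                "species": self.species,
                "region": self.region,
                "source": self.source,
                "model": self.model_id if self.model_id is not None else "",
                "member": self.member if self.member is not None else -1,
                "lead": self.lead_years if self.lead_years is not None else 0,
                "year": self.years,
                "area_km2": self.areas,
            }
        )

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.years.tolist(), self.areas.tolist()))


# ---------------------------------------------------------------------------
# Suitability indicators
# ---------------------------------------------------------------------------

def threshold_suitability(sst: GridField, model: ThresholdHabitatModel) -> GridField:
    """Binary cold-limit habitat: 1 where SST >= threshold (inclusive)."""
    if sst.variable != model.variable:
        raise GridError(
            f"{model.species} model expects {model.variable!r}, got {sst.variable!r}"
        )
    ind = (sst.values >= model.threshold).astype(float)
    ind = np.where(sst.mask, np.nan, ind)
    return sst.with_values(ind, variable="indicator")


def salinity_window_suitability(
    sal: GridField, model: SalinityWindowHabitatModel
) -> GridField:
    """Binary habitat: 1 where salinity is inside the closed window."""
    if sal.variable != model.variable:
        raise GridError(
            f"{model.species} model expects {model.variable!r}, got {sal.variable!r}"
        )
    lo, hi = model.window
    ind = ((sal.values >= lo) & (sal.values <= hi)).astype(float)
    ind = np.where(sal.mask, np.nan, ind)
    return sal.with_values(ind, variable="indicator")


# ---------------------------------------------------------------------------
# Probability model (pluggable) and its predictors
# ---------------------------------------------------------------------------

def default_dome_probability(lat, day_of_year, bathymetry, salinity, solar_elevation):
    """Simplified dome-shaped larval-occurrence probability.

    ``p = expit(2 - 200 (S - 35.4)^2)``: maximal (~0.88) at 35.4 psu and
    falling to 0.5 at the window edges 35.3/35.5 psu; zero over bathymetry
    shallower than 500 m (the species spawns along the shelf edge and over
    deep banks).  Latitude, day of year and solar elevation are accepted for
    interface compatibility but unused by this default.
    """
    salinity = np.asarray(salinity, dtype=float)
    p = expit(2.0 - 200.0 * (salinity - 35.4) ** 2)
    deep_enough = np.asarray(bathymetry, dtype=float) >= 500.0
    return np.where(deep_enough, p, 0.0)


_PROBABILITY_MODELS: dict[str, Callable] = {"default_dome": default_dome_probability}


def register_probability_model(name: str, fn: Callable) -> None:
    """Register a probability function of the five standard predictors."""
    _PROBABILITY_MODELS[name] = fn


def larvae_probability(
    lat,
    day_of_year,
    bathymetry,
    salinity,
    solar_elevation,
    model: SalinityWindowHabitatModel = BLUE_WHITING,
):
    """Probability of larval occurrence, in [0, 1], via the registered model.

    Deterministic; output is clipped to [0, 1] regardless of the plugged-in
    function.
    """
    name = model.probability_model or "default_dome"
    try:
        fn = _PROBABILITY_MODELS[name]
    except KeyError:
        raise GridError(
            f"probability model {name!r} is not registered "
            f"(known: {sorted(_PROBABILITY_MODELS)})"
        ) from None
    p = np.asarray(fn(lat, day_of_year, bathymetry, salinity, solar_elevation), dtype=float)
    return np.clip(p, 0.0, 1.0)


def solar_elevation(lat, day_of_year, hour_utc=12.0, lon=0.0):
    """Solar elevation angle in degrees.

    Declination and the equation of time use Spencer's Fourier series; the
    hour angle comes from local apparent solar time
    (UTC + lon/15 + EoT).  Accuracy is a few tenths of a degree, ample for a
    habitat-model predictor.
    """
    lat = np.radians(np.asarray(lat, dtype=float))
    n = np.asarray(day_of_year, dtype=float)
    g = 2.0 * np.pi * (n - 1.0) / 365.0
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    eot_min = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    solar_time = np.asarray(hour_utc, dtype=float) + np.asarray(lon, dtype=float) / 15.0 + eot_min / 60.0
    hour_angle = np.radians(15.0 * (solar_time - 12.0))
    sin_alpha = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)
    return np.degrees(np.arcsin(np.clip(sin_alpha, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# Habitat area and calibration
# ---------------------------------------------------------------------------

def habitat_area(
    indicator: GridField,
    region: RegionPolygon | np.ndarray,
    areas: np.ndarray | None = None,
) -> float:
    """Total suitable area in km²: sum of cell areas where the indicator is 1
    inside the region; masked cells contribute 0."""
    rmask = region if isinstance(region, np.ndarray) else region_mask(indicator.grid, region)
    if areas is None:
        areas = cell_areas(indicator.grid)
    suitable = (~indicator.mask) & rmask & (indicator.values >= 0.5)
    return float(np.sum(areas[suitable]))


def probability_area_curve(
    prob_fields: Mapping[int, GridField],
    region: RegionPolygon | np.ndarray,
    areas: np.ndarray | None = None,
) -> Callable[[float], dict[int, float]]:
    """Build ``threshold -> {year: habitat area}`` from probability fields.

    The returned callable thresholds each year's probability field at ``t``
    (inclusive, with p = 0 never suitable so that t = 0 means "any positive
    probability") and sums cell areas inside the region.
    """
    years = sorted(prob_fields)
    f0 = prob_fields[years[0]]
    rmask = region if isinstance(region, np.ndarray) else region_mask(f0.grid, region)
    if areas is None:
        areas = cell_areas(f0.grid)
    stacked = np.stack([prob_fields[y].masked_values() for y in years])
    cell = np.where(rmask, areas, 0.0)

    def curve(t: float) -> dict[int, float]:
        ok = np.isfinite(stacked) & (stacked >= t) & (stacked > 0)
        vals = (ok * cell).sum(axis=(1, 2))
        return dict(zip(years, vals.tolist()))

    return curve


def _q3(x: np.ndarray) -> float:
    # type-7 (linear interpolation of order statistics), numpy default
    return float(np.quantile(np.asarray(x, dtype=float), 0.75))


def calibrate_probability_threshold(
    prob_area_curve: Callable[[float], Mapping[int, float]],
    observed_distribution_areas: Mapping[int, float],
    thresholds: np.ndarray | None = None,
) -> float:
    """Probability cutoff matching habitat to observed distribution areas.

    Returns the threshold ``t*`` minimising
    ``|Q3(habitat areas at t) - Q3(observed areas)|`` over the overlapping
    years, searching a grid (default 0.001 steps in [0, 1]); ties go to the
    smallest threshold.  If the observed Q3 exceeds the largest attainable
    habitat Q3, the boundary value 0 is returned with a warning.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0 + 1e-12, 0.001), 3)
    obs_years = set(int(y) for y in observed_distribution_areas)
    areas0 = prob_area_curve(float(thresholds[0]))
    overlap = sorted(obs_years & set(int(y) for y in areas0))
    if not overlap:
        raise GridError("no overlapping years between habitat and observed distribution areas")
    obs_q3 = _q3([observed_distribution_areas[y] for y in overlap])
    diffs = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        areas = prob_area_curve(float(t))
        diffs[i] = abs(_q3([areas[y] for y in overlap]) - obs_q3)
    best = int(np.argmin(diffs))  # ties -> smallest threshold
    t_star = float(thresholds[best])
    max_q3 = _q3([areas0[y] for y in overlap])
    if obs_q3 > max_q3:
        warnings.warn(
            f"observed distribution Q3 ({obs_q3:.4g} km²) exceeds the largest attainable "
            f"habitat Q3 ({max_q3:.4g} km²); returning the boundary threshold {t_star}",
            stacklevel=2,
        )
    return t_star


def core_distribution_area(
    survey: Mapping[int, np.ndarray],
    areas: np.ndarray,
    fraction: float = 0.99,
) -> dict[int, float]:
    """Area of the core of the distribution, per year, from survey abundance.

    Cells are ranked by abundance (descending, stable in flat cell order so
    ties are resolved deterministically) and the smallest prefix holding at
    least ``fraction`` of the total abundance is kept.  All-zero years get
    area 0 with a warning.
    """
    out: dict[int, float] = {}
    for year in sorted(survey):
        ab = np.asarray(survey[year], dtype=float)
        if np.any(ab < 0):
            raise GridError(f"negative abundances in survey year {year}")
        total = np.nansum(ab)
        if total <= 0:
            warnings.warn(f"survey year {year} has zero total abundance", stacklevel=2)
            out[year] = 0.0
            continue
        flat = np.nan_to_num(ab).ravel()
        cellsz = np.asarray(areas, dtype=float).ravel()
        order = np.argsort(-flat, kind="stable")
        csum = np.cumsum(flat[order])
        k = int(np.searchsorted(csum, fraction * total - 1e-9 * total)) + 1
        out[year] = float(cellsz[order[:k]].sum())
    return out
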