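"""Forecast verification: r, MSESS, CRPS/CRPSS, bootstrap significance.

Skill of the habitat forecasts is quantified with three complementary
metrics over the verification pairs (forecast vs observation-derived habitat
area, matched by verification year):

* Pearson correlation *r* — phase agreement;
* MSESS, ``1 - MSE(forecast) / MSE(climatological mean)`` — accuracy
  relative to always forecasting the climatological-period mean;
* CRPSS, ``1 - CRPS(forecast) / CRPS(reference)`` — quality of the whole
  predictive distribution (all ensemble members), against a climatological
  reference distribution.  The reference is a Gaussian with the
  climatological-period mean and standard deviation of the observed habitat
  series (minimal two-parameter choice; an empirical-sample reference is
  also available).

Uncertainty comes from pairwise bootstrap resampling of years with
replacement (default 1000 replicates).  The same resampled year index sets
are reused across the metrics and forecast systems being compared, which is
what makes the paired one-tailed comparison (fraction of bootstrap draws in
which one system fails to beat the other) exact.

Degenerate inputs (zero-variance series, zero reference error) yield a
flagged-missing estimate (NaN + ``degenerate=True`` + a
:class:`DegenerateSeriesWarning`), never a silent NaN propagation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .grids import GridError, GridField

logger = logging.getLogger(__name__)

__all__ = [
    "VerificationPairSet",
    "SkillEstimate",
    "DegenerateSeriesWarning",
    "pearson_r",
    "msess",
    "crps_ensemble",
    "crps_gaussian",
    "crpss",
    "bootstrap_indices",
    "bootstrap_metric",
    "paired_comparison",
    "gridpoint_skill_map",
]

DEFAULT_N_BOOT = 1000


class DegenerateSeriesWarning(UserWarning):
    """A verification series was constant (or a reference error was zero)."""


@dataclass
class VerificationPairSet:
    """Aligned forecast/observed habitat values for one lead and window.

    ``members`` (n_years, n_members) is optional and only needed for CRPSS;
    ``forecast`` holds the deterministic (ensemble-mean) forecast.
    """

    years: np.ndarray
    forecast: np.ndarray
    observed: np.ndarray
    lead: int | None = None
    window: int = 1
    members: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.forecast = np.asarray(self.forecast, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        n = self.years.size
        if self.forecast.shape != (n,) or self.observed.shape != (n,):
            raise GridError("forecast/observed must match the number of years")
        if self.members is not None:
            self.members = np.asarray(self.members, dtype=float)
            if self.members.ndim != 2 or self.members.shape[0] != n:
                raise GridError("members must have shape (n_years, n_members)")

    @property
    def n(self) -> int:
        return self.years.size


@dataclass
class SkillEstimate:
    """A skill metric with its bootstrap distribution and significance."""

    metric: str
    estimate: float
    bootstrap: np.ndarray
    ci_level: float
    ci: tuple[float, float]
    p_gt0: float
    n: int
    lead: int | None = None
    window: int = 1
    degenerate: bool = False
    p_vs_baseline: float | None = None
    baseline: str | None = None

    def __post_init__(self) -> None:
        if self.ci[0] > self.ci[1]:
            raise GridError("CI bounds out of order")


def _degenerate(metric: str, reason: str) -> None:
    warnings.warn(f"{metric}: {reason}; skill reported as missing", DegenerateSeriesWarning,
                  stacklevel=3)


#: Relative scale below which a series is treated as constant.  Habitat areas
#: are O(1e5) km² and accumulate ulp-level float noise; variance that small is
#: numerical, not signal, and must be flagged rather than correlated.
_REL_TOL = 1e-9


def _effectively_constant(x: np.ndarray) -> bool:
    x = np.asarray(x, dtype=float)
    return bool(np.std(x) <= _REL_TOL * (np.abs(x).max() + 1.0))


# ---------------------------------------------------------------------------
# Point metrics
# ---------------------------------------------------------------------------

def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN (flagged) for constant series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise GridError("series lengths differ")
    if x.size < 3:
        raise GridError("pearson_r needs n >= 3")
    if _effectively_constant(x) or _effectively_constant(y):
        _degenerate("pearson_r", "zero-variance series")
        return np.nan
    xa, ya = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt(np.sum(xa**2)), np.sqrt(np.sum(ya**2))
    return float(np.sum(xa * ya) / (sx * sy))


def msess(forecast: np.ndarray, observed: np.ndarray, clim_mean: float) -> float:
    """Mean-squared-error skill score vs the climatological-mean forecast."""
    forecast = np.asarray(forecast, dtype=float)
    observed = np.asarray(observed, dtype=float)
    mse_f = np.mean((forecast - observed) ** 2)
    mse_ref = np.mean((clim_mean - observed) ** 2)
    scale = np.abs(observed).max() + abs(clim_mean) + 1.0
    if mse_ref <= (_REL_TOL * scale) ** 2:
        _degenerate("msess", "zero reference MSE")
        return np.nan
    return float(1.0 - mse_f / mse_ref)


def crps_ensemble(members: np.ndarray, observed: float) -> float:
    """CRPS of the empirical ensemble distribution against a scalar outcome.

    ``CRPS = (1/m) Σ|x_i − y| − (1/(2m²)) ΣΣ|x_i − x_j|`` — evaluated via the
    sorted-member identity (O(m log m)); tests check it against the O(m²)
    brute-force double sum.
    """
    x = np.sort(np.asarray(members, dtype=float).ravel())
    m = x.size
    if m == 0:
        raise GridError("empty ensemble")
    term1 = np.mean(np.abs(x - observed))
    i = np.arange(1, m + 1)
    pair_sum = 2.0 * np.sum((2 * i - m - 1) * x)  # = sum_ij |x_i - x_j|
    return float(term1 - pair_sum / (2.0 * m * m))


def crps_gaussian(mu: float, sigma: float, observed) -> np.ndarray | float:
    """Closed-form CRPS of a Gaussian: σ[z(2Φ(z)−1) + 2φ(z) − 1/√π]."""
    if sigma <= 0:
        raise GridError("crps_gaussian requires sigma > 0")
    z = (np.asarray(observed, dtype=float) - mu) / sigma
    out = sigma * (z * (2 * norm.cdf(z) - 1) + 2 * norm.pdf(z) - 1.0 / np.sqrt(np.pi))
    return float(out) if out.ndim == 0 else out


def _per_year_crps(pairs: VerificationPairSet) -> np.ndarray:
    if pairs.members is None:
        raise GridError("CRPSS needs member vectors in the pair set")
    return np.array(
        [crps_ensemble(pairs.members[i], pairs.observed[i]) for i in range(pairs.n)]
    )


def _reference_crps(
    observed: np.ndarray,
    clim_mean: float,
    clim_sd: float,
    reference: str | np.ndarray = "gaussian",
) -> np.ndarray:
    """Per-year CRPS of the climatological reference distribution."""
    if isinstance(reference, np.ndarray):
        return np.array([crps_ensemble(reference, y) for y in observed])
    if reference == "gaussian":
        if clim_sd <= _REL_TOL * (abs(clim_mean) + 1.0):
            _degenerate("crpss", "zero climatological spread")
            return np.full(observed.shape, np.nan)
        return np.asarray(crps_gaussian(clim_mean, clim_sd, observed))
    raise GridError(f"unknown CRPSS reference {reference!r}")


def crpss(
    pairs: VerificationPairSet,
    clim_mean: float,
    clim_sd: float,
    reference: str | np.ndarray = "gaussian",
) -> float:
    """CRPS skill score: ``1 − mean CRPS(forecast) / mean CRPS(reference)``.

    ``reference`` is either ``"gaussian"`` (climatological mean/sd) or an
    explicit sample array used as an empirical climatological ensemble.
    """
    crps_f = _per_year_crps(pairs)
    crps_ref = _reference_crps(pairs.observed, clim_mean, clim_sd, reference)
    denom = np.mean(crps_ref)
    if not np.isfinite(denom) or denom == 0:
        if np.isfinite(denom):
            _degenerate("crpss", "zero reference CRPS")
        return np.nan
    return float(1.0 - np.mean(crps_f) / denom)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_indices(n: int, n_boot: int = DEFAULT_N_BOOT, seed=None) -> np.ndarray:
    """(n_boot, n) year indices resampled with replacement.

    Generate once and reuse across every metric and forecast system being
    compared — the paired comparison requires identical resampled year sets.
    """
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(n_boot, n))


def _boot_pearson(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    xb, yb = x[idx], y[idx]
    xa = xb - xb.mean(axis=1, keepdims=True)
    ya = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xa**2).sum(axis=1) * (ya**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (xa * ya).sum(axis=1) / denom, np.nan)


def bootstrap_metric(
    pairs: VerificationPairSet,
    metric: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed=None,
    indices: np.ndarray | None = None,
    ci_level: float = 0.90,
    clim_mean: float | None = None,
    clim_sd: float | None = None,
    reference: str | np.ndarray = "gaussian",
) -> SkillEstimate:
    """Pairwise bootstrap of a skill metric over verification years.

    Years are resampled with replacement (forecast and observed jointly),
    the metric recomputed per replicate, the CI taken from percentiles, and
    the one-tailed p-value against zero is the fraction of the bootstrap
    sample <= 0.  Pass ``indices`` to share resamples across metrics.
    """
    if pairs.n < 3:
        raise GridError("bootstrap_metric needs at least 3 verification pairs")
    if indices is None:
        indices = bootstrap_indices(pairs.n, n_boot, seed)
    f, o = pairs.forecast, pairs.observed

    if metric == "pearson_r":
        point = pearson_r(f, o)
        boot = _boot_pearson(f, o, indices)
    elif metric == "msess":
        if clim_mean is None:
            raise GridError("msess needs clim_mean")
        point = msess(f, o, clim_mean)
        se_f = (f - o) ** 2
        se_ref = (clim_mean - o) ** 2
        ref_b = se_ref[indices].mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            boot = np.where(ref_b > 0, 1.0 - se_f[indices].mean(axis=1) / ref_b, np.nan)
    elif metric == "crpss":
        if clim_mean is None or clim_sd is None:
            raise GridError("crpss needs clim_mean and clim_sd")
        point = crpss(pairs, clim_mean, clim_sd, reference)
        crps_f = _per_year_crps(pairs)
        crps_ref = _reference_crps(o, clim_mean, clim_sd, reference)
        ref_b = crps_ref[indices].mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            boot = np.where(ref_b > 0, 1.0 - crps_f[indices].mean(axis=1) / ref_b, np.nan)
    else:
        raise GridError(f"unknown metric {metric!r}")

    degenerate = not np.isfinite(point)
    finite = boot[np.isfinite(boot)]
    if finite.size == 0 or degenerate:
        return SkillEstimate(metric, np.nan, boot, ci_level, (np.nan, np.nan), np.nan,
                             pairs.n, lead=pairs.lead, window=pairs.window, degenerate=True)
    alpha = 1.0 - ci_level
    ci = (float(np.quantile(finite, alpha / 2)), float(np.quantile(finite, 1 - alpha / 2)))
    p_gt0 = float(np.mean(finite <= 0.0))
    return SkillEstimate(metric, point, boot, ci_level, ci, p_gt0, pairs.n,
                         lead=pairs.lead, window=pairs.window)


def paired_comparison(boot_a: np.ndarray, boot_b: np.ndarray) -> float:
    """One-tailed significance that system A exceeds system B.

    ``p = (1/N) Σ 1{a_i <= b_i}`` over paired bootstrap draws (same resampled
    year sets); small p means A beats B consistently.  Ties count as "not
    exceeding" (conservative), so identical samples give p = 1.
    """
    a = np.asarray(boot_a, dtype=float)
    b = np.asarray(boot_b, dtype=float)
    if a.shape != b.shape:
        raise GridError("paired bootstrap samples must have equal size")
    ok = np.isfinite(a) & np.isfinite(b)
    if not np.any(ok):
        return np.nan
    return float(np.mean(a[ok] <= b[ok]))


# ---------------------------------------------------------------------------
# Grid-point skill maps
# ---------------------------------------------------------------------------

def gridpoint_skill_map(
    forecast_fields: Sequence[GridField],
    observed_fields: Sequence[GridField],
    n_boot: int = DEFAULT_N_BOOT,
    ci_level: float = 0.95,
    seed=None,
    indices: np.ndarray | None = None,
) -> tuple[GridField, GridField]:
    """Per-cell correlation map with one-tailed bootstrap significance.

    Returns ``(r, significant)`` fields: *r* is the per-cell Pearson
    correlation over years, and *significant* is 1 where r is significantly
    greater than 0 at the given confidence level (fraction of bootstrap
    resamples <= 0 below ``1 - ci_level``).  Cells masked anywhere in either
    series, or with a constant series, are masked (degenerate).
    """
    if len(forecast_fields) != len(observed_fields) or len(forecast_fields) < 3:
        raise GridError("need >= 3 aligned (forecast, observed) field pairs")
    grid = forecast_fields[0].grid
    fa = np.stack([f.values for f in forecast_fields])  # (n, nlat, nlon)
    oa = np.stack([f.values for f in observed_fields])
    mask = np.any(np.stack([f.mask for f in list(forecast_fields) + list(observed_fields)]), axis=0)
    n = fa.shape[0]

    def cellwise_r(f: np.ndarray, o: np.ndarray) -> np.ndarray:
        famu = f - f.mean(axis=0)
        oamu = o - o.mean(axis=0)
        denom = np.sqrt((famu**2).sum(axis=0) * (oamu**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (famu * oamu).sum(axis=0) / denom, np.nan)

    r = cellwise_r(fa, oa)
    degenerate = ~np.isfinite(r)

    if indices is None:
        indices = bootstrap_indices(n, n_boot, seed)
    n_le0 = np.zeros(grid.shape)
    n_ok = np.zeros(grid.shape)
    for block in np.array_split(indices, max(1, len(indices) // 100)):
        rb = np.stack([cellwise_r(fa[idx], oa[idx]) for idx in block])
        finite = np.isfinite(rb)
        n_ok += finite.sum(axis=0)
        n_le0 += ((rb <= 0) & finite).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_ok > 0, n_le0 / n_ok, np.nan)
    significant = (p < (1.0 - ci_level)) & ~degenerate & ~mask

    out_mask = mask | degenerate
    r_field = GridField(grid, "probability", np.where(out_mask, np.nan, r), mask=out_mask)
    sig_field = GridField(grid, "indicator", np.where(out_mask, np.nan, significant.astype(float)),
                          mask=out_mask)
    return r_field, sig_field
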