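"""Climatologies, lead-dependent full-field bias correction, ensemble means.

Decadal prediction systems drift: their systematic bias depends on how far
the forecast has run from its initialised state, so the model climatology is
computed *per lead time* and indexed by verification year, making it directly
comparable with the observational climatology over the same reference period
(default 1985-2014).  The full-field scheme then replaces the model's own
climate with the observed one, member by member::

    corrected = member - model_clim(lead) + obs_clim

which guarantees the drift-removal identity: the reference-period mean of
corrected forecasts at any (model, lead) equals the observational
climatology.  Only the mean is adjusted — no variance or quantile scaling,
and no start-date dependence (one initialisation per year).

Verification-year convention: a forecast issued 1 January of start year *s*
verifies calendar year ``s + lead - 1`` in the target month, i.e. lead 1 is
the start year itself.  Configurable via ``ForecastSet.verif_offset``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .grids import GridError, GridField, GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "Climatology",
    "ForecastSet",
    "REFERENCE_PERIOD",
    "observational_climatology",
    "forecast_climatology",
    "bias_correct",
    "bias_correct_set",
    "ensemble_mean",
    "grand_ensemble_mean",
]

#: Default 30-year reference period for all climatologies (inclusive).
REFERENCE_PERIOD = (1985, 2014)


@dataclass
class Climatology:
    """Per-month mean field over a fixed reference period.

    ``lead_years is None`` marks an observational climatology; forecast
    climatologies additionally carry ``model_id`` and ``lead_years``.
    """

    grid: GridSpec
    variable: str
    month: int
    period: tuple[int, int]
    mean: np.ndarray
    mask: np.ndarray
    lead_years: int | None = None
    model_id: str | None = None

    def __post_init__(self) -> None:
        if self.period[0] > self.period[1]:
            raise GridError(f"empty reference period {self.period}")
        self.mean = np.asarray(self.mean, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mean.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise GridError("climatology arrays do not match grid shape")

    def as_field(self) -> GridField:
        return GridField(self.grid, self.variable, self.mean, mask=self.mask)


class ForecastSet:
    """Initialized-hindcast fields of one model: (start_year, member, lead).

    Backed by a dense array ``values[start, member, lead, lat, lon]`` so that
    climatologies and corrections vectorise; :meth:`get` returns individual
    :class:`~habcast.grids.GridField` views.
    """

    def __init__(
        self,
        model_id: str,
        grid: GridSpec,
        variable: str,
        month: int,
        start_years: Sequence[int],
        leads: Sequence[int],
        n_members: int,
        values: np.ndarray,
        mask: np.ndarray | None = None,
        verif_offset: int = -1,
    ) -> None:
        self.model_id = model_id
        self.grid = grid
        self.variable = variable
        self.month = int(month)
        self.start_years = np.asarray(start_years, dtype=int)
        self.leads = np.asarray(leads, dtype=int)
        if self.leads.min() < 1:
            raise GridError("lead years must be >= 1")
        self.n_members = int(n_members)
        self.values = np.asarray(values, dtype=float)
        expected = (
            self.start_years.size,
            self.n_members,
            self.leads.size,
        ) + grid.shape
        if self.values.shape != expected:
            raise GridError(f"forecast values shape {self.values.shape} != {expected}")
        self.mask = (
            ~np.isfinite(self.values)
            if mask is None
            else np.asarray(mask, dtype=bool) | ~np.isfinite(self.values)
        )
        #: verification year = start_year + lead + verif_offset
        self.verif_offset = int(verif_offset)

    def verification_year(self, start_year: int, lead: int) -> int:
        return start_year + lead + self.verif_offset

    def _idx(self, start_year: int, lead: int) -> tuple[int, int]:
        s = np.flatnonzero(self.start_years == start_year)
        l = np.flatnonzero(self.leads == lead)
        if s.size == 0:
            raise KeyError(f"start year {start_year} not in {self.model_id}")
        if l.size == 0:
            raise KeyError(f"lead {lead} not in {self.model_id}")
        return int(s[0]), int(l[0])

    def get(self, start_year: int, member: int, lead: int) -> GridField:
        s, l = self._idx(start_year, lead)
        year = self.verification_year(start_year, lead)
        return GridField(
            self.grid,
            self.variable,
            self.values[s, member, l],
            time=(year, self.month),
            mask=self.mask[s, member, l],
        )

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "ForecastSet":
        return ForecastSet(
            self.model_id,
            self.grid,
            self.variable,
            self.month,
            self.start_years,
            self.leads,
            self.n_members,
            values,
            mask=self.mask if mask is None else mask,
            verif_offset=self.verif_offset,
        )


# ---------------------------------------------------------------------------
# Climatologies
# ---------------------------------------------------------------------------

def observational_climatology(
    fields: Sequence[GridField], period: tuple[int, int] = REFERENCE_PERIOD
) -> Climatology:
    """Grid-point mean of one month's fields over the reference period.

    Every year of the period must be present; the mask is the union of the
    per-year masks.
    """
    by_year = {f.year: f for f in fields}
    years = list(range(period[0], period[1] + 1))
    missing = [y for y in years if y not in by_year]
    if missing:
        raise GridError(f"observational climatology missing years: {missing}")
    months = {f.month for f in fields if f.year in years}
    if len(months) != 1:
        raise GridError(f"climatology mixes months: {sorted(months)}")
    sel = [by_year[y] for y in years]
    stack = np.stack([f.values for f in sel])
    mask = np.any(np.stack([f.mask for f in sel]), axis=0)
    mean = np.where(mask, np.nan, stack.mean(axis=0))
    f0 = sel[0]
    return Climatology(f0.grid, f0.variable, months.pop(), tuple(period), mean, mask)


def forecast_climatology(
    fc: ForecastSet, lead: int, period: tuple[int, int] = REFERENCE_PERIOD
) -> Climatology:
    """Mean over all (start_year, member) whose *verification* year is in the
    reference period, at the given lead — one climatology per (model, lead).

    All (year, member) pairs are pooled with equal weight.
    """
    _, l = fc._idx(fc.start_years[0], lead)
    verif = fc.start_years + lead + fc.verif_offset
    sel = (verif >= period[0]) & (verif <= period[1])
    needed = set(range(period[0], period[1] + 1))
    have = set(int(v) for v in verif[sel])
    missing = sorted(needed - have)
    if missing:
        raise GridError(
            f"{fc.model_id} lead {lead}: no start years verifying in {missing}"
        )
    vals = fc.values[sel, :, l]  # (years, members, lat, lon)
    mask = np.any(fc.mask[sel, :, l], axis=(0, 1))
    mean = np.where(mask, np.nan, vals.mean(axis=(0, 1)))
    return Climatology(
        fc.grid, fc.variable, fc.month, tuple(period), mean, mask,
        lead_years=int(lead), model_id=fc.model_id,
    )


# ---------------------------------------------------------------------------
# Bias correction
# ---------------------------------------------------------------------------

def bias_correct(
    member_field: GridField, model_clim: Climatology, obs_clim: Climatology
) -> GridField:
    """Full-field correction of one member field.

    ``corrected = member − model_clim + obs_clim`` cellwise; the output mask
    is the union of the three input masks.
    """
    if model_clim.lead_years is None:
        raise GridError("model climatology must carry a lead time")
    if obs_clim.lead_years is not None:
        raise GridError("observational climatology must not carry a lead time")
    for clim in (model_clim, obs_clim):
        if clim.grid != member_field.grid:
            raise GridError("climatology grid does not match the member field grid")
    mask = member_field.mask | model_clim.mask | obs_clim.mask
    corrected = member_field.values - model_clim.mean + obs_clim.mean
    corrected = np.where(mask, np.nan, corrected)
    return member_field.with_values(corrected, mask=mask)


def bias_correct_set(
    fc: ForecastSet,
    obs_clim: Climatology,
    period: tuple[int, int] = REFERENCE_PERIOD,
) -> ForecastSet:
    """Apply the full-field correction to every member at every lead."""
    out = np.empty_like(fc.values)
    out_mask = np.zeros_like(fc.mask)
    for j, lead in enumerate(fc.leads):
        clim = forecast_climatology(fc, int(lead), period)
        out[:, :, j] = fc.values[:, :, j] - clim.mean + obs_clim.mean
        out_mask[:, :, j] = fc.mask[:, :, j] | clim.mask | obs_clim.mask
    out[out_mask] = np.nan
    logger.info(
        "bias-corrected %s: %d starts x %d members x %d leads",
        fc.model_id, fc.start_years.size, fc.n_members, fc.leads.size,
    )
    return fc.with_values(out, mask=out_mask)


# ---------------------------------------------------------------------------
# Ensemble aggregation
# ---------------------------------------------------------------------------

def ensemble_mean(fields: Sequence[GridField]) -> GridField:
    """Unweighted cellwise mean over member fields sharing one grid."""
    if len(fields) == 0:
        raise GridError("ensemble_mean of an empty member set")
    f0 = fields[0]
    for f in fields[1:]:
        if f.grid != f0.grid:
            raise GridError("ensemble members are on different grids")
    stack = np.stack([f.values for f in fields])
    mask = np.any(np.stack([f.mask for f in fields]), axis=0)
    return f0.with_values(np.where(mask, np.nan, stack.mean(axis=0)), mask=mask)


def grand_ensemble_mean(
    sets: Iterable[ForecastSet], start_year: int, lead: int
) -> GridField:
    """Equal-weight mean over every member of every model ("Grand Ens.").

    Each realisation counts once irrespective of which system it came from,
    so models with more members carry proportionally more weight.
    """
    members: list[GridField] = []
    for fc in sets:
        members.extend(fc.get(start_year, m, lead) for m in range(fc.n_members))
    return ensemble_mean(members)
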