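"""Reference (baseline) forecasts for habitat metrics.

A habitat forecast is only useful if it beats the cheap alternatives, so the
verification compares initialized predictions against:

* **persistence** — the habitat metric of the issue year propagated
  unchanged out to the 10-year horizon ("tomorrow is the same as today"),
* **multi-year binned means** — centred 3/5/9-year moving averages, with the
  forecast time at the centre of the window (both forecast and observed
  series are binned, then paired by centre year), and
* **uninitialized projections** — free-running climate simulations that share
  the external forcing (and hence the trend) but were never synchronised to
  the observed ocean state; one realisation per model, no lead dependence.

Baselines operate on the scalar habitat-area series, not on fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import GridError
from .habitat import HabitatSeries

logger = logging.getLogger(__name__)

__all__ = [
    "PersistenceForecast",
    "BinnedSeries",
    "persistence",
    "binned_mean",
    "align_uninitialized",
]


@dataclass
class PersistenceForecast:
    """The issue year's habitat metric carried forward to every lead."""

    issue_year: int
    value: float
    max_lead: int = 10

    def forecast(self, lead: int) -> float:
        if not 0 <= lead <= self.max_lead:
            raise GridError(f"lead {lead} outside 0..{self.max_lead}")
        return self.value


@dataclass
class BinnedSeries:
    """Centred ``window``-year moving average, keyed by window-centre year.

    Values exist only where the full window is available.
    """

    window: int
    years: np.ndarray
    values: np.ndarray

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.years.tolist(), self.values.tolist()))


def persistence(series: HabitatSeries, max_lead: int = 10) -> dict[int, HabitatSeries]:
    """Per-lead persistence forecasts from an observed habitat series.

    ``forecast(issue_year, lead) = observed(issue_year)``, stamped with
    verification year ``issue_year + lead``; lead 0 (if requested via
    ``max_lead >= 0``) is the identity.  Verification pairs are formed
    downstream by matching years against observations, giving exactly
    ``n - L`` pairs at lead ``L`` for an ``n``-year gap-free series.
    """
    out: dict[int, HabitatSeries] = {}
    for lead in range(1, max_lead + 1):
        out[lead] = HabitatSeries(
            species=series.species,
            region=series.region,
            source="persistence",
            years=series.years + lead,
            areas=series.areas.copy(),
            lead_years=lead,
        )
    return out


def binned_mean(series: Mapping[int, float] | HabitatSeries, window: int) -> BinnedSeries:
    """Centred moving average; edge years with incomplete windows omitted."""
    if window % 2 == 0 or window < 1:
        raise GridError(f"binning window must be odd and >= 1, got {window}")
    if isinstance(series, HabitatSeries):
        data = series.as_dict()
    else:
        data = {int(y): float(v) for y, v in series.items()}
    years = sorted(data)
    s = pd.Series([data[y] for y in years], index=years)
    # contiguity matters: reindex over the full span so gaps poison windows
    full = s.reindex(range(years[0], years[-1] + 1))
    binned = full.rolling(window, center=True, min_periods=window).mean().dropna()
    return BinnedSeries(window, binned.index.to_numpy(dtype=int), binned.to_numpy())


def align_uninitialized(
    projections: Mapping[str, Mapping[int, float] | HabitatSeries],
    verification_years: Sequence[int],
) -> tuple[np.ndarray, list[str]]:
    """Per-year ensemble of projected habitat metrics.

    Returns ``(values, model_ids)`` with ``values`` of shape
    ``(n_years, n_models)``: for each verification year, the habitat metric
    of each model's single realisation for that calendar year.  Projections
    carry no lead dependence; they must be bias-corrected against the same
    observational climatology (lead-independent correction) upstream.
    """
    years = np.asarray(list(verification_years), dtype=int)
    model_ids = sorted(projections)
    values = np.empty((years.size, len(model_ids)))
    for j, mid in enumerate(model_ids):
        series = projections[mid]
        data = series.as_dict() if isinstance(series, HabitatSeries) else {
            int(y): float(v) for y, v in series.items()
        }
        missing = [int(y) for y in years if int(y) not in data]
        if missing:
            raise GridError(f"projection {mid!r} missing verification years {missing}")
        values[:, j] = [data[int(y)] for y in years]
    return values, model_ids
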