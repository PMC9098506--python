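# Methods

This note records the models, conventions and numerical choices behind
`habcast`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Gridded data model

Fields live on regular lat–lon grids with cell-centre registration and
half-open cells `[centre − Δ/2, centre + Δ/2)`; longitudes are normalised to
`[−180, 180)` (antimeridian-crossing polygons must be supplied as
multi-part rings). A boolean mask marks missing cells; values are finite
wherever unmasked.

* **Depth averaging.** Sub-surface salinity arrives on depth layers; the
  250–600 m mean weights each layer by the thickness of its overlap with
  the range, skipping masked layers per column. Columns with zero
  overlapping unmasked thickness become masked. The result always lies
  between the per-column layer extremes (convexity).
* **Bilinear regridding.** Standard 4-point interpolation from the source
  cell centres. Masked source cells *poison* the target: any target point
  whose stencil touches a masked cell is masked, with no partial-weight
  renormalisation. This is deliberately conservative near coastlines; the
  alternative (renormalising over the unmasked stencil) extrapolates ocean
  values over land and was rejected. Target points outside the source
  centre hull are masked.
* **Cell areas.** `A = R² Δλ (sin φ_top − sin φ_bottom)` with
  R = 6371.0 km (configurable; a conventional mean Earth radius — the
  choice only rescales all areas uniformly and cancels in every skill
  metric). The global sum reproduces 4πR² to < 0.01%.
* **Region membership.** A cell belongs to a region iff its *centre* is
  inside (boundary inclusive, via shapely). Centre containment keeps
  areas additive over disjoint polygons; fractional cell overlap was
  rejected as spurious precision at half-degree resolution. Latitude caps
  ("south of 70 °N") are encoded as polygon edges, not separate filters.

## 2. Climatology and bias correction

All climatologies average 1985–2014 (inclusive; configurable). Forecast
climatologies are computed per (model, lead) and indexed by **verification
year** so model and observational climatologies average the same target
years — this is what makes the full-field scheme an exact drift remover:
for every model and lead, the reference-period mean of corrected members
equals the observational climatology (machine precision; asserted at
1e-10 in tests).

Conventions:

* Verification year = start year + lead − 1 (forecasts issued 1 January;
  lead 1 verifies the start year's target month). Exposed as
  `ForecastSet.verif_offset` because prediction systems differ in start
  month.
* Mean-only correction: no variance or quantile adjustment, and no
  start-date dependence (one initialisation per year).
* Forecast climatologies pool all (year, member) pairs with equal weight;
  with constant member counts this equals averaging per-year member means.
* The grand ensemble weights every member equally, so it equals the
  member-count-weighted mean of per-model ensemble means (asserted
  algebraically in tests). Mean-of-model-means aggregation is out of
  scope.
* Uninitialized projections get the same full-field correction with a
  single lead-independent climatology, paralleling the initialized
  treatment.

## 3. Habitat models

Threshold comparisons are **boundary-inclusive** (≥ 8.5 °C, ≥ 11 °C,
closed window 35.3–35.5 psu); strictness is not determined by the science
and inclusive is fixed here once. Ties in practice occur with probability
zero on continuous fields.

The blue whiting larval-occurrence probability model is a pluggable
function of (latitude, day of year, bathymetry, solar elevation angle,
salinity), registered by name. The published model's coefficients are not
available, so the default is a documented simplified dome:
`p = expit(2 − 200 (S − 35.4)²)` — maximum ≈ 0.88 at 35.4 psu, 0.5 at the
window edges — zeroed where bathymetry < 500 m (shelf-edge spawner); the
other predictors pass through unused. The binary salinity window is the
science-anchored fallback and is what the default pipeline uses. Solar
elevation comes from Spencer's Fourier-series declination and equation of
time (accuracy a few tenths of a degree, ample for a habitat predictor).

**Probability-threshold calibration.** A probability model needs a cutoff
before its habitat area can be compared with adult distribution areas. The
cutoff minimises `|Q3(annual habitat areas at t) − Q3(observed annual
distribution areas)|` over the overlapping years, searching t in 0.001
steps on [0, 1]; ties take the smallest threshold, and an unattainable
observed Q3 returns the boundary 0 with a warning. Minimised distance was
chosen over exact equality because the area-vs-threshold curve is a step
function. Q3 is the type-7 (linear-interpolation) sample quantile.

**Core distribution area.** Survey cells are ranked by abundance
(descending, stable in flat cell order) and the smallest prefix holding
≥ 99% of total abundance is kept. Equal-abundance cells beyond the prefix
are *not* pulled in: with 100 equal cells at fraction 0.99 the area is 99
cells, and the stable sort makes the selection deterministic. The area is
invariant to uniform rescaling of abundances.

## 4. Reference forecasts

* **Persistence** operates on the scalar habitat-area series:
  forecast(issue, L) = observed(issue), paired with observed(issue + L),
  giving n − L pairs per lead. On an AR(1) metric the persistence
  correlation at lead L is φ^L, which the tests verify against Bartlett's
  sampling variance.
* **Binned means** are centred odd-window moving averages keyed by the
  window-centre year; incomplete windows (edges, gaps) are omitted. Both
  forecast and observed series are binned, then paired by centre year.
  Member series are binned individually; by linearity this commutes with
  ensemble averaging (asserted in tests).
* **Uninitialized projections** provide one realisation per model, aligned
  by calendar year with no lead dependence.

## 5. Verification

Comparison periods: 1961–2018 for SST-based habitat, 1985–2018 for
salinity-based habitat (earlier sub-surface salinity observations are not
trustworthy enough to verify against). Within the pipeline, the pairing
years for a given (species, lead, window) are the intersection of all
compared sources, so every system is scored on identical years.

* MSESS and CRPSS references use the mean and standard deviation (ddof=1)
  of the *observed* habitat series over the climatological period,
  computed on the binned series for binned skill. The CRPSS reference
  distribution is Gaussian — the minimal two-parameter family consistent
  with "mean and standard deviation"; an empirical-sample reference is
  also available (`reference=` argument).
* Ensemble CRPS uses the sorted-member identity (O(m log m)), equal to the
  pairwise double sum at 1e-12 (tested against the brute-force oracle);
  Gaussian CRPS uses the closed form σ[z(2Φ(z)−1) + 2φ(z) − 1/√π].
* Bootstrap: pairwise resampling of years with replacement, 1000
  replicates, percentile CIs (no BCa — plain percentiles are what the
  resampling scheme defines); one-tailed p against zero = fraction of
  replicates ≤ 0. A single seeded generator produces the index sets,
  which are reused across metrics and systems; the paired comparison
  `p = mean(a_i ≤ b_i)` is then exact, with ties conservatively counted
  as "not exceeding" (identical samples give p = 1).
* Grid-point maps report per-cell r with a one-tailed bootstrap
  significance mask at 95%. No field-significance or multiple-testing
  correction is applied across cells.
* **Degenerate series** (constant habitat areas, zero reference error) are
  flagged and reported missing rather than propagated as NaN or spurious
  correlations. Because habitat areas are O(1e5) km² sums that accumulate
  ulp-level float noise, "constant" is decided at a relative tolerance of
  1e-9 times the series scale, not exact zero variance.

## 6. The synthetic world

The generator's defaults are the stated experimental conditions, fixed
once:

| Parameter | Default | Why |
| --- | --- | --- |
| Domain | 40 × 60 cells at 0.5°, 45–65°N, 30°W–0° | northern North Atlantic box at the common analysis resolution, desk-scale |
| Years | 1960–2018 | matches the SST verification span |
| Truth | trend + AR(1) + white noise per cell | the minimal decomposition with a predictable low-frequency component |
| φ (AR1) | 0.8 | strong decadal memory, the regime where initialization pays off |
| SST | base 12.5 °C, −0.35 °C/°lat, trend 0.25 °C/decade, σ_lf 0.35, σ_hf 0.30 | gradient spans both isotherms inside the domain; noise levels give persistence skill that fades over ~5 years |
| Salinity | base 35.52, −0.01 psu/°lon, trend −0.008 psu/decade, σ_lf 0.03, σ_hf 0.012 | gradient spans the 35.3–35.5 window; freshening trend |
| Ensemble | 5 models × 3 members, leads 1–10 | five-system structure at desk scale; the real-world grand ensemble (85 members) is reachable via `members_per_model` |
| Drift | b(model, lead) = offset + linear drift, scales 0.5 °C / 0.05 psu | lead-dependent bias the correction must remove |
| ρ(lead) | 0.9 × 0.93^(lead−1) | predictable fraction, non-increasing by construction |
| Survey | effort 1000, lognormal σ 0.3, 2° × 1° grid | multiplicative observation error typical of acoustic surveys |

Hindcast members blend the truth's low-frequency phase (weight ρ) with an
independent surrogate AR(1) (weight 1 − ρ) plus member noise; uninitialized
runs share the forced trend but run on their own phase. Spatial loadings
are smooth order-one harmonics so isotherm/isohaline geometry stays
analytically tractable.

What the generator does **not** emulate: ocean dynamics, spatially
correlated observation error, curvilinear native grids, missing-data
patterns of real reanalyses, non-Gaussian extremes. A green test therefore
establishes that the *machinery* (correction identities, metric
definitions, calibration, bootstrap) is correct under the stated
statistical structure — not that any real stock's habitat is predictable.

## 7. Determinism and budgets

Every random draw flows from a single integer seed through named
`numpy` SeedSequence sub-streams (truth / hindcasts / survey / bootstrap
per species-lead-window / maps), so `verify` is a pure function of
(inputs, config, seed) and reruns are byte-identical. The default pipeline
(3 species × 10 leads × 4 windows × 1000 bootstrap replicates plus two
2400-cell skill maps) runs in well under a minute on one CPU; tests use
smaller worlds throughout.

## 8. Known limitations

* Binned forecast skill bins the fixed-lead series across verification
  years; the alternative (averaging leads within one start, centre-lead
  labelling) is not implemented and matters only for comparing directly
  against decadal multi-year-mean products.
* The default pipeline uses the binary salinity window for blue whiting;
  the calibrated probability route is exercised by the library and tests
  but not wired into `run_verify`.
* Masked-cell poisoning plus centre containment can under-count habitat
  along coastlines relative to fractional-cell schemes.
* The percentile bootstrap slightly under-covers for strongly skewed
  statistics (|r| near 1, n small); the coverage test documents the
  achieved rate rather than assuming nominal coverage.
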