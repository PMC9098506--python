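# habcast

Decadal-scale forecasting and verification of marine fish habitat from
gridded ocean hindcast ensembles.

Many fish stocks are shifting their distribution as the ocean changes, on
exactly the 1–10-year horizon where fishing communities, businesses and
treaty negotiators make decisions. Initialized decadal climate predictions
have real skill for North Atlantic SST and sub-surface salinity on that
horizon; `habcast` turns such predictions into *habitat-area* forecasts for
three exemplar species and scores them rigorously against
observation-derived habitat:

* **Mackerel** — suitable where mean August SST ≥ 8.5 °C (cold range limit);
* **Bluefin tuna** — suitable where mean August SST ≥ 11 °C (foraging limit);
* **Blue whiting** — spawning habitat where the March 250–600 m mean
  salinity lies in 35.3–35.5 psu (a pluggable larval-occurrence probability
  model with quartile calibration against survey distribution areas is also
  provided).

The package is aimed at marine-ecological forecasting researchers who want
the full verification chain — not just the metrics — reproducible end to end.

## The method

For each prediction system, member fields at lead *k* years are
**full-field bias corrected**:

```
corrected = member − clim_model(model, k) + clim_obs
```

where both climatologies average the same verification years of the
reference period (1985–2014). This removes model bias *and* lead-dependent
drift: after correction, the reference-period mean forecast equals the
observed climatology at every grid cell, for every model and lead.

Habitat models are applied to the corrected fields, and the area of
suitable habitat inside a study polygon (spherical cell areas, cell-centre
containment) becomes the forecast metric. The **grand ensemble** pools all
members from all systems with equal weight. Verification against
observation-derived habitat uses:

* Pearson correlation *r*;
* `MSESS = 1 − MSE(forecast) / MSE(climatological mean)`;
* `CRPSS = 1 − CRPS(ensemble) / CRPS(climatological Gaussian)`, with the
  empirical-ensemble CRPS
  `CRPS = (1/m)Σ|xᵢ−y| − (1/(2m²))ΣΣ|xᵢ−xⱼ|`;

relative to persistence, climatology and uninitialized-projection baselines,
for single years and 3/5/9-year centred means. Uncertainty comes from
pairwise bootstrap resampling of years (1000 replicates); the same
resampled year sets are shared across forecast systems so that "does the
grand ensemble beat persistence?" is answered by an exact paired one-tailed
comparison.

Real inputs (SST/salinity reanalyses, DCPP-style hindcast archives, CMIP6
projections, spawning-stock surveys) are hundreds of gigabytes, so the
package ships a first-class synthetic generator
(`habcast.synthetic_data`) producing a statistically analogous world:
trend + AR(1) low-frequency signal + white noise, hindcasts with imposed
lead-dependent drift and a decaying predictable fraction, projections that
share the trend but not the phase, and a thinned survey field.

## Worked example

```python
from habcast import RunConfig, run_verify

res = run_verify(RunConfig(out_dir="out", seed=42))
sk = res["skill"]
print(sk[(sk.species == "mackerel") & (sk.metric == "pearson_r")
         & (sk.window == 1) & (sk.lead.isin([1, 3, 5, 10]))]
      [["source", "lead", "estimate", "ci_lo", "ci_hi", "p_vs_baseline"]])
```

On the default synthetic world this prints (values rounded):

```
        source  lead  estimate  ci_lo  ci_hi  p_vs_baseline
grand_ensemble     1     0.999  0.999  0.999          0.0
   persistence     1     0.922  0.892  0.947          NaN
grand_ensemble     3     0.996  0.994  0.998          0.0
   persistence     3     0.830  0.763  0.890          NaN
grand_ensemble     5     0.992  0.989  0.994          0.0
   persistence     5     0.756  0.687  0.824          NaN
grand_ensemble    10     0.971  0.957  0.981          0.0
   persistence    10     0.509  0.402  0.615          NaN
```

The grand-ensemble correlation stays high at decadal leads while
persistence fades with the autocorrelation of the low-frequency signal;
`p_vs_baseline = 0.0` means the grand ensemble beat persistence in every
one of the 1000 paired bootstrap replicates. `ci_lo`/`ci_hi` bound the 90%
percentile interval and `p_gt0` is the one-tailed significance against
zero skill. Binned forecasts sharpen further: the 9-year mean at lead 5
reaches r = 0.996 here. `out/` also receives the tidy habitat series
(`habitat_series.csv`, areas in km² per species/source/lead/year) and
grid-point skill maps (`skill_map_sst.nc`, `skill_map_salinity.nc` with
per-cell r and bootstrap significance).

From the shell, the same pipeline is:

```bash
habcast simulate --config cfg.yaml --out world/   # netCDF truth + hindcasts + survey
habcast verify   --config cfg.yaml --seed 42      # skill tables + maps
```

## Acceptance script

`scripts/acceptance.py` re-runs the entire chain from scratch — synthetic
world generation, depth averaging, bias correction, habitat metrics for all
three species, baseline construction, and the bootstrap skill tables — at
the default scale and writes the results manifest:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The verification outputs land next to the manifest in
`results/acceptance_run/`.

## Layout

| Module | Role |
| --- | --- |
| `habcast.grids` | grid/field containers, depth averaging, bilinear regridding, cell areas, polygon masks, netCDF/GeoJSON/WKT I/O |
| `habcast.climatology_bias` | climatologies, lead-dependent full-field correction, ensemble means |
| `habcast.habitat` | species habitat models, habitat area, probability-threshold calibration, core-99% distribution area |
| `habcast.references` | persistence, centred binned means, uninitialized-projection alignment |
| `habcast.skill` | r / MSESS / CRPS / CRPSS, bootstrap CIs, paired comparisons, grid-point skill maps |
| `habcast.synthetic_data` | the synthetic world generator |
| `habcast.cli` | `RunConfig`, the end-to-end pipeline, click CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
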