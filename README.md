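# noiselur

Land-use-regression (LUR) modelling of urban environmental noise, end to
end: from minute-resolution A-weighted sound-level logs and geospatial
predictor layers to mixed-effect LAeq_1hr models, city-wide noise surfaces
(LAeq_24hr, L_den, L_day, L_night), intermittency-ratio statistics, and
enumeration-area population-exposure and socioeconomic-inequality
summaries.

The package targets the measurement design of large urban noise campaigns
in rapidly growing cities — many short-term rotating monitors plus a few
long-term fixed ones — where the goal is a citywide annual-average exposure
surface for epidemiology and policy. Because raw campaign data of this kind
are rarely public, the package ships a first-class synthetic-city generator
with a known acoustic ground truth, so every stage of the pipeline is
validated against a recoverable answer.

## The model

Sound levels combine on the energy scale. A set of levels `L_i` (dBA) over
equal intervals has equivalent continuous level

    LAeq = 10 log10( (1/n) Σ_i 10^(L_i/10) ).

Minute logs are aggregated to LAeq_1hr, and long-term hourly profiles to
the standard period metrics: L_day (06:00–21:59), L_night (22:00–05:59),
LAeq_24hr, and the day–evening–night level

    L_den = 10 log10( (1/24) [ Σ_day 10^(L_h/10)
                             + Σ_evening 10^((L_h+5)/10)
                             + Σ_night 10^((L_h+10)/10) ] ),

with day 06–18, evening 19–21, night 22–05. A flat 24 h profile at X dBA
gives L_den = X + 6.305 dBA.

Hourly levels at site *s*, hour *h* follow a Gaussian linear mixed model
with crossed random intercepts,

    L_sh = β0 + Σ_k β_k x_ks + γ·height_s + a_h + b_s + ε_sh,

where `x_ks` are standardized buffer-based spatial covariates (road lengths
by class, land-cover areas, NDVI, points of interest, population density,
distances to roads and the airport), `a_h ~ N(0, σ_h²)` and
`b_s ~ N(0, σ_s²)`. Separate models are fitted for day and night hours by
profiled REML (a dedicated crossed-random-effects solver, cross-checked
against statsmodels). Model selection is the two-step LUR procedure: per
variable, the buffer radius most correlated with site-level mean levels
(with an a-priori sign screen), then forward stepwise on the fixed-effect
R² with a 1% minimum gain, a stability prune of wide zero-crossing
coefficients, a challenge round, and an |r| > 0.8 collinearity filter.

Validation is out-of-site by construction: 10-fold and leave-one-site-out
cross-validation hold out whole monitoring sites, and Moran's I checks the
site residuals for spatial structure. The fitted models predict 24 hourly
surfaces on a 50 m grid (masked to in-sample areas: no water, no roadless
grassland/forest), aggregated per cell to the period metrics. Surfaces are
overlaid on census enumeration areas to bin population into 5 dBA exposure
classes, measure exceedance of the WHO road-traffic guidance (L_den 53,
L_night 45 dBA), and contrast noise across quintiles of area socioeconomic
status (Pearson r with Fisher-z intervals; Welch test between extreme
quintiles).

The intermittency ratio (IR) summarises how eventful a soundscape is: the
percentage of a period's acoustic energy contributed by minutes at least
3 dBA above the period's own LAeq. IR is computed per site and modelled
with the same selection machinery on site-level linear models.

## Worked example

```
noiselur all --config noiselur.yaml
```

with a desk-scale configuration (1.5 km synthetic city, 44 sites):

```yaml
seed: 17
city: {extent_m: [1500, 1500], n_eas: 20}
sites: {n_rotating: 40, n_fixed: 4, rotating_days: 2, fixed_days: 3}
cv_scheme: cv10_sites
output_dir: run1
```

prints, among other stage reports:

```
LAeq_1hr model, night hours (n=736 site-hours, 44 sites)
  R2 (fixed effects, squared correlation): 0.892
  sigma2 site / hour / residual: 2.36 / 0.89 / 0.97
  Intercept: 53.7 [48.6, 58.7]
  ndvi_50: -2.64 [-3.16, -2.11]
  secondary_tertiary_road_length_200: 4.36 [3.34, 5.37]
  ...
day cv10_sites: MAE 1.58 dBA, ME -0.10 dBA, r 0.94
l_den: 100.0% of population above 53.0 dBA
day Moran's I 0.010 (E[I] -0.023, p 0.173)
```

Each coefficient is the change in LAeq_1hr (dBA) per standard deviation of
the covariate; vegetation (NDVI in a 50 m buffer) lowers night levels by
~2.6 dBA per SD while secondary/tertiary road length raises them. The CV
line is the pooled out-of-site error: mean absolute error 1.58 dBA with a
near-zero mean error, and Moran's I near its null expectation −1/(n−1)
indicates no residual spatial structure. The `run1/` directory holds the
city layers (GeoJSON/ASC), minute and hourly CSVs, model JSONs with the
full selection trace, CV tables, surface rasters, exposure and inequality
CSVs, plots, and the resolved configuration for provenance.

Library use mirrors the CLI: `generate_city` → `place_sites` →
`simulate_minute_levels` → `hourly_levels` → `extract_features` →
`forward_stepwise` → `cross_validate` → `predict_surfaces` →
`ea_average` / `exposure_distribution` / `ses_inequality`.

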