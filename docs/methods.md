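# Methods

## Scope and design

`noiselur` implements a complete noise land-use-regression (LUR) study at
desk scale. The chain is: synthetic city with known acoustic ground truth →
minute-level measurement simulation → energy-based acoustic metrics →
buffer-based spatial features → crossed-random-intercepts mixed models with
two-step forward selection → site-grouped cross-validation and spatial
diagnostics → gridded prediction surfaces → enumeration-area (EA)
population exposure and socioeconomic inequality. Every stage is a public
module; the CLI is a thin orchestration layer.

## Acoustic metrics

All aggregation is energetic: levels are converted to relative energy
`10^(L/10)`, averaged, and converted back. Clock conventions (no daylight
saving): day 06:00–21:59 (16 h), night 22:00–05:59 (8 h); L_den splits the
day block into unpenalised day hours 06–18 and evening hours 19–21 (+5 dBA),
with +10 dBA on night hours. A flat profile at X dBA therefore has
L_den = X + 10·log10((13 + 3·10^0.5 + 80)/24) ≈ X + 6.305 dBA — used as a
closed-form check throughout the tests.

Long-term hourly profiles average across days on the energy scale,
consistent with equivalent-continuous-level semantics (an arithmetic dBA
mean across days would be a different, smaller quantity; the choice is a
package decision since either convention appears in practice). Hours with
no minutes are omitted, never imputed; `n_minutes` records coverage.
Site-level period aggregates are only computed for sites whose long-term
profile covers all 24 hours.

The intermittency ratio of a period is the percentage of total energy in
minutes at or above `LAeq(period) + C`, with C = 3 dBA by default. At
1-minute integration the event unit is necessarily the minute: sub-minute
event reconstruction (as done with 1 s data in the original formulation of
the metric) is not possible, and short events inside an otherwise quiet
minute are diluted. IR values here are therefore conservative for highly
impulsive soundscapes.

## Synthetic city and ground truth

The generator builds roads (major arterials, secondary/tertiary spans,
short minor segments), a 4-class land-cover raster (20 m) driven by road
proximity plus smooth noise, NDVI (30 m) anti-correlated with road
proximity by construction, a smooth DEM, points of interest and building
centroids clustered near roads, Voronoi enumeration areas partitioning the
extent, optional lakes, and an airport polygon. Defaults: 4×4 km extent,
40 EAs, ~3% water. The NDVI field deliberately mixes a short-range smooth
component with white noise at the native 30 m resolution: satellite NDVI
has strong cell-scale texture (individual trees, roofs, plots), and that
texture is what makes buffer means at nearby radii (50 vs 100 m)
statistically distinguishable — a prerequisite for buffer selection to be a
meaningful exercise at all.

EA population and socioeconomic attributes derive from the zonal mean of an
arterial-road proximity score over each EA polygon: population density
rises with it, log household consumption falls with it (poorer, denser
settlement along loud corridors), education counts rise and unemployment
falls with consumption, all with lognormal/logistic noise. This builds the
exposure-inequality phenomenon into the city by construction; its strength
in any one realisation is an outcome, not an input.

Ground truth for sound: site base level = intercept + Σ β_k·z_k(site) with
β on the scale of published urban LUR models (roads a few +dBA per SD,
NDVI a few −dBA per SD), a fixed diurnal profile (mean-zero within the day
and night blocks separately, plus a −7 dBA night offset), site intercepts
N(0, 2²), minute residuals N(0, 3²), and Poisson sound events (2/h by
default) that add 10 dBA energetically to their minute. Monitoring sites
are placed by stratified random sampling over land-cover classes
(proportional quotas, floor of two per class, never in water), with mount
heights 4 ± 1 m. Defaults follow the campaign design: 136 rotating sites at
7 days, 10 fixed sites at 30 days (a desk-scale stand-in for year-long
monitoring; the unbalanced design is preserved, the seasonal span is not).

What the generator does *not* emulate: traffic micro-dynamics, weather,
building-canyon propagation and barriers, temporally varying sources, and
measurement error of the instruments. Passing tests therefore demonstrate
the statistical machinery recovers a linear-in-features truth under
realistic noise — not that the fitted models capture real acoustic
propagation.

## Feature extraction

Buffers are closed disks at 50/100/200/500 m (boundary features count;
point-in-buffer uses exact distances, not the polygonal buffer
approximation). Line layers contribute clipped length, land-cover classes
contribute cell-centre-counted area, NDVI contributes its buffer mean with
negative (water) cells omitted, point layers contribute count and presence,
population contributes the area-weighted mean EA density, and distance and
√distance are computed to the nearest major road, secondary road, and the
airport. When a buffer is smaller than a raster's resolution and catches no
cell centre, the location's own cell value is used (floored at 0 for NDVI).

Standardization is z-scoring with the sample (n−1) SD, fitted on the
monitoring sites and stored; prediction locations are always transformed
with the stored parameters, and a parameter mismatch at prediction time is
a hard error. Count and presence variables stay raw (their units are
interpretable as-is). Constant columns cannot be standardized and are
dropped from the candidate set with a warning.

## Mixed model and estimation

The hourly model has crossed random intercepts for site and hour-of-day.
No installed Python library fits crossed Gaussian random effects
efficiently, so the solver is implemented here: the two variance ratios are
profiled out of the REML criterion and optimised (L-BFGS-B seeded by a
coarse grid, simplex polish); each criterion evaluation works on
precomputed Gram matrices through the Woodbury identity and costs
O((S+H)³), independent of the number of observations. Fixed-effect
covariances are conditional on the estimated variance parameters (Wald
intervals with normal quantiles — site counts here make the t/z distinction
negligible). Hour intercepts enter predictions as BLUPs. The solver is
verified in the test suite against statsmodels' variance-component
formulation of the same model on a small dataset (estimates agree to four
decimals), and against closed-form behaviour in degenerate cases.

Model R² is reported two ways, since mixed-model R² has no single
definition: `r2_fixed`, the squared Pearson correlation between
fixed-effect predictions and observed hourly levels (used by the selection
rule), and a marginal variant (fixed-effect variance over total variance).

## Selection procedure

Step one screens each variable: the buffer with the largest |Pearson r|
against site-level period mean levels wins (ties below 1e-6 go to the
smaller, more local buffer); variables whose realised sign contradicts the
a-priori expectation (roads/activity +, vegetation/formal-residential −)
are excluded. Screening uses site-level means, not hourly rows, to avoid
pseudo-replication. Step two is forward stepwise on `r2_fixed` with a 0.01
minimum gain, followed by a stability prune — a variable is dropped when
its 95% CI crosses zero *and* the CI half-width exceeds the coefficient
magnitude (|t| < 1); a zero-crossing CI alone is not disqualifying — then a
challenge round re-offering every excluded candidate, and a pairwise
collinearity filter (|r| > 0.8 keeps the variable closer to the outcome).
Every decision is appended to a selection trace stored with the model.
Monitor height is always included as an adjustment covariate (silently
skipped only if constant in the fitted subset, where it is unidentifiable).

## Evaluation

Cross-validation partitions sites (10 folds or leave-one-site-out);
held-out predictions use fixed effects plus training-data hour intercepts,
never a site intercept. Metrics (median/mean absolute error, mean error, r,
r²) are pooled over all held-out site-hours. By default the final variable
set is refit per fold; optional per-fold re-selection is available. The
feature standardization is not refit per fold — parameters come from the
full site set, matching common LUR practice; the leakage is limited to
column scaling. Moran's I uses row-standardised inverse-distance weights
without a cutoff and a seeded 999-permutation p-value (one-sided on the
observed side of E[I] = −1/(n−1)); at least 8 sites are required for the
weight matrix to be meaningful.

## Surfaces and exposure

The prediction grid (default 50 m) masks out cells intersecting water and
cells entirely of 'other' land cover with no road (the "fully
grassland/forest" reading: any road in the cell keeps it in-sample). Hour
h's surface uses the day model for h ∈ 6..21 and the night model otherwise,
each with its hour intercept, at a fixed 4 m monitor height. Per-cell
aggregates are computed by the very same scalar code path as the acoustics
module, so the aggregation identity holds bit-for-bit.

EA averages are arithmetic on dBA over masked-in cell centres (the
convention for area exposure summaries; an energetic variant is available
behind a flag and always dominates the arithmetic one by Jensen's
inequality). Each EA's whole population is assigned to the 5 dBA bin
[5k, 5k+5) of its mean level — no within-EA dasymetric allocation — making
population conservation exact by construction. Guideline exceedance uses
L_den 53 / L_night 45 dBA. SES quintiles are rank-based with stable
tie-breaking on EA id (sizes differ by at most one; any strictly increasing
transform of the measure yields the same grouping); correlations carry
Fisher-z intervals `tanh(atanh r ± 1.96/√(n−3))`; the difference-in-means
test is Welch's (no equal-variance assumption), comparing the extreme
quintiles by default.

## Numerical choices and degenerate inputs

- λ (variance-ratio) search bounded in log space [−16, 12]; at the lower
  bound the model degenerates gracefully to OLS-like behaviour.
- Singular fixed-effect designs raise errors naming constant columns and
  duplicated pairs; perfect collinearity in VIF reports ∞.
- Hours or periods with no data raise value errors rather than returning
  NaN; `-inf` hourly levels (zero energy) propagate correctly through the
  penalty sums (absent energy adds nothing).
- Determinism: every stochastic step takes an explicit seed; the CLI fans a
  single run seed into per-stage child seeds via `SeedSequence.spawn`, so
  stages are independently re-runnable and full reruns are bit-identical.

## Problem sizes

Defaults are chosen for a desktop: a 4×4 km extent (6,400 prediction cells
at 50 m), 146 sites, 7/30 measurement days, and replicate counts of 30–50
in the simulation-based tests. All sizes are configuration, not code;
larger extents and longer campaigns only cost time.

## Known limitations

- The IR models inherit the weakness noted above: temporally static spatial
  predictors explain intermittency only indirectly, and site-level sample
  sizes make those fits prone to overfitting; their R² should be read as
  descriptive.
- Wald intervals ignore variance-parameter uncertainty; at ≥ 100 sites the
  effect on coverage is within Monte-Carlo error of nominal in the test
  suite.
- The generator's linear truth means model misspecification (nonlinearity,
  interactions in the noise field) is untested by design.
- A single planar CRS in metres; no geodesic computation, no reprojection.
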