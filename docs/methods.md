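# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer would otherwise
have to reverse-engineer.

## Fix filtering and panels

Transmitters report at most one fix per hour between 0500 and 2000 local
standard time. Both endpoints are scheduled slots, so the window filter
is inclusive; local time is a fixed UTC offset (no daylight-saving
logic), configurable at ingest for data recorded in UTC. Duplicate
(bird, timestamp) rows keep the first occurrence, because a transmitter
emits one fix per slot. A bird-month panel is retained only with
`min_fixes ≥ 100` (default), which guards against months fragmented by
recapture; months are calendar months in local time. Manufacturer GPS
error (±18 m) is far below the 100 m analysis grid and is not modeled.

## Kernel utilization distributions

The UD is a bivariate isotropic Gaussian kernel density evaluated at
cell centers of a regular grid (100 m default) and renormalized to unit
mass. Cell-center evaluation (not cell integration) is standard for this
grid/bandwidth regime; the grid pads the point cloud by `3h`, which
keeps truncated mass below 1e-3 before renormalization, and the grid
origin snaps to multiples of the cell size so UDs align with co-gridded
rasters without resampling error. Evaluation exploits the kernel's
separability (`values = G_y G_xᵀ`), which the test suite checks against
a direct per-cell summation oracle at 1e-10 relative tolerance.

The reference bandwidth is the bivariate-normal reference rule
`h_ref = sqrt((s_x² + s_y²)/2) · n^(−1/6)` with sample SDs (ddof = 1).
Least-squares cross-validation is deliberately not implemented: it is
known to collapse on telemetry with many duplicate roost/perch
locations, the very regime this analysis targets.

The home range is the 99% volume isopleth — the smallest set of
highest-density cells whose cumulative mass reaches the level (ties
broken by stable sort order, so results are deterministic). Contiguity
uses 8-connectivity between selected cells, matching the polygon
contiguity of common GIS tools; boundary polygons are traced along cell
edges on demand. Because mass accumulates in whole cells, the contained
mass slightly exceeds the level; the documented tolerance band is
[0.985, 0.995] at the 0.99 level.

The ad-hoc bandwidth scans multipliers of `h_ref` (default 0.1…1.0 in
steps of 0.1, ascending) and returns the smallest whose 99% isopleth has
one connected component. Each multiplier is evaluated independently — no
monotonicity of contiguity in `h` is assumed — and the scan shares one
padded grid extent so candidate isopleths are comparable. If even 1.0
fragments (possible for multi-cluster synthetic data), the scan
escalates in 0.1 steps to 2.0 and then fails loudly rather than
returning a fragmented home range. Selection is per bird-month by
default; a global multiplier can be forced via configuration
(`global_multiplier`) when a study-wide choice is preferred.

## Selection ratios

Within a panel's home range, availability of a unit (habitat class or
ecoregion) is its share of home-range cells — cells are equal-area, so
this is the area share. Use is the probability of occurrence in the
unit. Two use estimators are provided:

- **UD mass** (`use_estimator="ud"`, default in the pipeline): the UD
  probability mass over the unit's cells, renormalized over the home
  range. This is the classical UD-based estimator.
- **Fix counts** (`use_estimator="counts"`): the fraction of the panel's
  fixes falling in the unit's home-range cells.

The two differ in a way that matters: kernel smoothing moves mass across
patch boundaries, so the UD-mass estimator *attenuates* ln(rf) whenever
patch size is not much larger than the bandwidth. In the recovery
experiments (1 km patches, ~1 km ad-hoc bandwidths) the attenuation of
contrasts reaches 60–70%; the count estimator has no such bias and is
what the calibration studies use. On real landscapes with habitat
patches much wider than the bandwidth the two converge. This attenuation
is a genuine limitation of UD-ratio designs worth keeping in mind when
interpreting absolute ln(rf) magnitudes.

Units with zero availability in a panel are excluded (no comparison is
possible); zero use with positive availability leaves ln(rf) undefined —
the record is flagged NaN and excluded from modeling rather than patched
with a pseudo-count (an optional `use_floor` exists but defaults off).
Use is renormalized over the 99% region; the alternative (raw UD mass)
differs by at most the excluded 1%.

Ecoregion polygons are rasterized to the UD grid by cell-center tests,
preserving categorical labels. Landcover reclassification (fine survey
legend → 12 habitat classes) is a user-supplied mapping; the shipped
`EXAMPLE_LANDCOVER_MAPPING` is a synthetic stand-in for a real
crosswalk, which is survey-specific configuration.

## Meteorological covariates

- Thermal height: convective boundary-layer depth (km), read directly
  from forecast-model boundary-layer height under convective conditions.
- Thermal velocity: the convective velocity scale
  `w* = (g·z_i·Q₀/θ)^(1/3)` with g = 9.81 m/s², boundary-layer depth
  `z_i` (m), surface kinematic heat flux `Q₀` (K·m/s) and CBL mean
  potential temperature `θ` (K). Negative flux (stable stratification)
  clips to w* = 0 with a warning.
- Boundary-layer mean wind: trapezoid integration of the speed profile
  over [0, z_i] divided by z_i, constant below the lowest level.

Daily mid-day values average to (year, month) means and then across
years, so years with unequal coverage weigh equally. Ecoregion means are
unweighted over every 12 km cell intersecting the ecoregion with
positive area ("overlap" membership, not cell-center-in-polygon);
ecoregions overlapping no cell drop out with a warning. Forecast-format
decoding (GRIB/NetCDF) is out of scope — pipelines ingest long-format
CSV of precomputed cell values, which the synthetic generator emits
directly.

## Mixed models and multimodel inference

The response is ln(rf) per bird-month(-unit), modeled as

    y_it = x_itᵀβ + u_i + e_it,  u_i ~ N(0, σ_u²),
    corr(e_it, e_it') = ρ^{|t−t'|}

with integer month lags (gaps allowed), or compound symmetry (u_i alone
carries within-bird correlation). Fits profile β out by GLS and optimize
the 2–3 variance parameters (log variances, atanh ρ) by Nelder-Mead from
method-of-moments starts — fully deterministic. The implementation is
cross-checked against R's `nlme::lme` with `corAR1` (ML and REML) in the
test suite.

Two estimation methods serve two purposes:

- **ML** for the AICc candidate set (information criteria require full
  ML), with `k` counting fixed effects plus variance parameters and
  `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`.
- **REML** for hypothesis tests on fixed effects: with tens of birds,
  ML variance components are biased low and Wald tests become badly
  anticonservative (measured ~11% Type I at nominal 1% in a 12-bird
  null study).

Wald F tests use between-within denominator degrees of freedom: terms
constant within a bird (sex, age, release site…) test against
`n_birds − p_between`, time-varying terms against
`n − n_birds − p_within`. This replaces the Kenward–Rogers machinery of
the motivating SAS workflow; with REML it calibrates the P < 0.01 screen
to ≈1% Type I error in the null study. The screen uses a strict
inequality (p = 0.01 exactly is not flagged). Multiple-comparison
adjustment for marginal-mean contrasts is Bonferroni (an option), not
Tukey–Kramer — exact studentized-range machinery was judged out of
scope.

Marginal (least-squares) means average model predictions over a balanced
grid of the other categorical terms with continuous terms at their data
means, so unbalanced sampling does not tilt level means. Treatment
(reference-level) coding is used throughout; aliased terms are dropped
greedily before fitting (small panels routinely alias factors, e.g.
every breeder being an adult).

The ecoregion candidate set holds the bird-characteristic terms in every
model and distinguishes candidates by the 2³ subsets of
{thermal_height, thermal_velocity, wind_speed}. Month as a categorical
base term is deliberately excluded from this model set: with
climatological (multi-year-average) monthly covariates, a categorical
month factor aliases the meteorology exactly, and season enters through
the covariates themselves. Model averaging is shrinkage (full-set):
models lacking a parameter contribute estimate 0 with variance 0, the
unconditional SE is `sqrt(Σ w_i (var_i + (β_i − β̄)²))`, and importance
is the summed weight of models containing the parameter; conditional
averaging is available by flag. CIs are ±1.96 SE.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:

- **Landscape**: Voronoi patches of a seeded point process (mean patch
  diameter `patch_scale`) with classes assigned round-robin, so
  availability proportions are near-equal and every class is present;
  ecoregions are equal vertical bands.
- **Tracks** (`point_process` mode): fixes i.i.d. from density
  ∝ `K_hr(x) · w[h(x)]`, with `K_hr` an isotropic Gaussian home-range
  kernel (default SD 5 km) centered per bird. The expected selection
  ratio is then `ln w_j − ln Σ_k a_k w_k` in closed form, the recovery
  target. A `biased_walk` mode (correlated walk with per-step rejection
  by habitat weight) provides serially correlated tracks.
- **Schedule**: hourly fixes 0500–2000 (≤16/day), optional random
  dropout at a configurable rate (real fix-success rates are unknown; no
  fidelity is claimed).
- **Meteorology**: per-parameter seasonal sinusoids with offset peaks
  (thermal height peaking mid-summer, wind in spring), an optional
  west–east gradient, and month-to-month noise so the three covariates
  are not mutually collinear in downstream models.
- **Attributes**: marginals default to a realistic telemetry sample
  (43 M / 31 F; release sites 53/27/20%); immature birds never breed.

Not emulated: roost fidelity, carcass-driven aggregation, GPS error,
behavioral responses to weather. Passing tests therefore demonstrate the
*estimators* are correct and calibrated under the assumed structure, not
that real condor data satisfy that structure.

Coordinates are planar meters throughout; real lon/lat telemetry should
be projected to a metric equal-area CRS before ingest.

## Validation experiment sizing

Experiment sizes were set by power considerations so Monte Carlo error
sits well inside the documented tolerances, while each study completes
in tens of seconds on one core:

- Recovery: 20 birds × 1 month × full July schedule (496 fixes), 3
  classes with weights (1, 2, 4), 1 km patches; per-bird contrast noise
  ~0.1 gives SE ≈ 0.03 over 20 birds against a ±0.1 tolerance.
- Null calibration: 20 birds × 2 months, uniform weights; SE of each
  class mean ≈ 0.014 against a ±0.05 bound.
- Screen Type I: 25 birds × 8 months per replicate, replicates until
  ≥1000 null term tests; at 12 birds the between-bird df are so small
  the test becomes visibly conservative, at 25 the empirical rate sits
  at the nominal 1%.
- Coverage / covariance selection: 100 replicates of 40 birds × 12
  months, ρ = 0.6, slope 1.0.

All studies and the acceptance script derive their seeds from a single
`--seed`, and every fit is deterministic, so reruns reproduce results
exactly.

## Known limitations

- UD-mass use attenuates ln(rf) at patch scales comparable to the
  bandwidth (see above); the count estimator sidesteps this but ignores
  the UD's smoothing of location error.
- Between-within df are an approximation; Kenward–Rogers or Satterthwaite
  per-contrast df would be preferable at very small bird counts.
- The AR(1) structure assumes evenly interpretable integer month lags;
  irregular within-month sampling is collapsed to one observation per
  bird-month-unit before modeling.
- Cross-unit dependence (use summing to 1 across units within a panel)
  is not modeled, mirroring the motivating design.
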