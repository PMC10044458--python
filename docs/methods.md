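# Methods

This note records the models implemented in `thermozone`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Index computation

The heat-stress index is the quadratic form
`THI = (6.3952 + 0.08964·Tair + 0.01018·Ws)²` with `Tair` in °C and `Ws`
in m s⁻¹.  Two conventions needed fixing:

- **Mean air temperature.** `Tair = (Tmax + Tmin)/2`, the standard
  midpoint convention for gridded products that ship only the extremes.
- **Annual aggregation.** Annual THI is the *index of annual means*: one
  evaluation per point-year from that year's mean `Tair` and `Ws`.  The
  form is convex in its argument, so the mean of monthly indices would be
  slightly larger; the index-of-means reading matches how annual summary
  fields are produced from annual climatologies.  Monthly aggregation is
  deliberately not simulated (see below).

Note the index's name notwithstanding, this variant has a wind term and no
humidity term; it is implemented exactly as written.  Internally THI is
never rounded; report writers round to 2 decimals.

## Semivariogram estimation and fitting

The Matheron estimator is binned into `n_lags = 12` uniform distance
classes out to `max_dist` = half the maximum pairwise distance (both
config-exposed; these mirror common GIS defaults).  Two conventions:

- **Lag centers are mean pair distances.**  On a regular lattice the pair
  distances inside a bin are far from uniform; labeling the bin with its
  geometric midpoint misattributes the estimate and biases the fitted
  nugget upward.  Using the mean pair distance per bin (the `gstat`
  convention) removed that bias in the round-trip simulations; empty bins
  keep their midpoint and are skipped by the fitter.
- **Zero-distance pairs are excluded** (duplicate coordinates trigger a
  warning): they carry no information about γ at h > 0.

Fitting is bounded least squares on `(C₀, C, a)` with Cressie weights
`N(h)/γ_model(h)²`, expressed as residuals `√N (γ_emp − γ_mod)/γ_mod`.
Three starts (method-of-moments; flat/high-nugget; steep/short-range)
guard against local minima; the winner has the lowest weighted SSE, ties
broken by lower nugget.  Bounds: `C₀, C ≥ 0` (so nugget ≤ sill by
construction), `a` within [lag_width/10, 3·max_dist].  The reported
`fit_r2` is computed in semivariogram space (1 − SSE/SStot over non-empty
bins), an explicit package convention.  A constant field degenerates to a
zero pure-nugget model rather than an error.

The exponential and gaussian families use the practical-range −3 scaling,
so both reach `C₀ + 0.95·C` at `h = a`; the spherical model attains its
sill exactly at `a`.  `γ(0) = 0` with a jump to `C₀` as `h → 0⁺`.

## Ordinary kriging

Semivariogram-form ordinary kriging with the whole nugget inside γ and
`γ(0) = 0` on the system diagonal; predictions at coordinates coinciding
with a sample bypass the solve and return the sample value with σ = 0
(exact-interpolation convention).  The neighborhood is global by default —
at desk scale (≤ 5000 points) one LU factorization serves every target —
with an optional local search (`max_n`, `radius_m`) for larger inputs;
cells with fewer than two neighbors become no-data.  Negative kriging
variances from round-off are clipped at zero with a warning.  Rasters are
written as ESRI ASCII grids with cell centers on the sampling lattice and
−9999 as the no-data sentinel.

## Cross-validation

Leave-one-out with the variogram model fitted once on the full year of
data (per-fold refitting is available as an option but is not the
convention in GIS cross-validation and is ~n× costlier).  Folds are
computed exactly, not approximately: removing row i from the augmented
kriging matrix is a Schur-complement update of its inverse B, under which
the fold's weights collapse to `−B[:,i]/B[i,i]`, the LOO error to
`(B·[y,0])[i]/B[i,i]` and the fold variance to `−1/B[i,i]`.  One matrix
inverse therefore yields all n folds (O(n³) total); the test-suite asserts
exact agreement with brute-force per-fold re-solves.

Error statistics over folds, with `e = obs − pred`: ME, MAE, the
*standardized mean error* `mean(e/σ)` (reported under the traditional
"MSE" column name — the signed near-zero values this statistic takes are
only coherent without squaring), `ASE = mean(σ)`, RMSE, and
`RMSSE = √mean((e/σ)²)`.  ASE is the plain mean of σ, not an RMS.
Selection prefers RMSSE closest to 1, then smallest |RMSE − ASE|, then
smallest |ME| (ties below 10⁻⁶ cascade); final ties fall back to the
declared family order spherical < exponential < gaussian, which makes the
winner invariant to input permutation.

## Zoning

Suitability is inclusive: a cell suits a breed when `THI ≤ limit`, so a
breed operating exactly at its critical limit counts as suitable.  A
subregion is "usable" when 100 % of its valid cells are suitable
(`min_fraction` relaxes this, and per-subregion percentages are always
reported, because near-misses — e.g. a region 95 % below a limit — are
decision-relevant).  Regional CDFs are empirical, inclusive by default
(`cdf_at(t) = #{x ≤ t}/n`), with strict comparison available.  Multi-year
reporting periods default to quadrennia (2010–2013, 2014–2017, 2018–2021)
and are config-exposed.

## Descriptive statistics

Sample (n−1) standard deviation; bias-corrected sample skewness and
*excess* kurtosis (normal ≈ 0); CV classes low < 12 % ≤ medium ≤ 24 % <
high (both boundaries in "medium", per the closed-interval convention);
quartiles by linear interpolation (type 7).  Normality uses the
Kolmogorov–Smirnov test with the Lilliefors correction, since the
reference normal's parameters are estimated from the sample and the plain
KS p-value would be anti-conservative; α = 0.01.  Normality is reported,
never asserted, downstream.  Constant samples get skewness/kurtosis 0 by
convention and are flagged untestable for normality.

## Synthetic data generator

The generator emulates the *statistical structure* of an annual gridded
climate export: a rectangular study area partitioned into named vertical
strips, a regular 4-km point lattice, and per-variable stationary Gaussian
random fields whose semivariogram is one of the three families, realized
by dense Cholesky factorization of `C(h) = sill − γ(h)` (guarded at
≤ 5000 points, with a 10⁻¹⁰·sill diagonal jitter).  Tmax, Tmin and Ws are
independent fields redrawn independently each year; physical constraints
are enforced afterwards (Tmin clipped to Tmax − 0.2 °C, Ws truncated at
0).  All outputs are pure functions of (config, seed), with one spawned
child seed per (year, variable).

Demo defaults (units, value, why):

- Tmax / Tmin means 29 / 19 °C — a 10 °C annual diurnal-mean amplitude
  with statewide `Tair ≈ 24` °C, which at the 1.5 m s⁻¹ default wind puts
  THI near 73, the middle of the observed 66–79 band.
- gaussian variograms, nugget 0.15, sill 1.8 (°C²), range 60 km — the
  magnitudes recovered from annual THI fields of this kind; a −0.01 °C/km
  westward trend stands in for the coastal–interior contrast.
- wind: exponential, mean 1.5 m s⁻¹, sill 0.15, range 50 km.

What the generator does **not** emulate: cross-correlation between the
three variables (no cross-covariances were available to calibrate one; an
independent-fields assumption is conservative for THI variance), monthly
seasonality (the analysis operates on annual means), inter-year
persistence (years are independent draws), coastline/elevation geometry,
and non-Gaussian tails.  Passing tests therefore demonstrate correctness
of the estimators and the pipeline under a known stationary
Gaussian-field truth — not fidelity of any particular real territory.

## Calibration study conditions

The acceptance study simulates the THI field directly: gaussian variogram,
nugget 0.13, sill 1.7 (THI²), range 60 km, mean 73, on the 676-point
lattice (26 × 26 at 4 km, i.e. a 100 × 100 km domain), 10 seeds.  These
sizes keep a dense-covariance simulation and an exact LOO tractable on a
single CPU while leaving ≥ 10 lattice spacings per range.  Expected
behavior, asserted by the acceptance tests and recomputed by
`scripts/acceptance.py`: mean RMSSE of the correctly specified family in
[0.8, 1.2]; |RMSE − ASE|/ASE < 0.25; the generating family selected in
most seeds; nugget/sill/range recovered within ±30 % on the 10-seed mean.
Because the domain is only ~1.7 ranges wide, single-seed fits can wander
(sill and range trade off along the ridge of the WLS objective); the
±30 % band reflects that finite-domain reality, and model selection can
occasionally (≈ 1–3 seeds in 10) prefer a misspecified family whose RMSSE
lands nearer 1 by chance.

## Known limitations

- Isotropic, single-structure variograms only; no anisotropy, nesting, or
  universal kriging.  A strong spatial trend in the data therefore leaks
  into the fitted range (visible in demo years where the trend pushes the
  selected family to exponential with a long range).
- The kriging-variance convention places the whole nugget in γ
  (no measurement-error split); σ at an exact sample location is 0.
- Planar-meter coordinates are assumed everywhere; real exports must be
  projected before ingestion (lon/lat columns are carried but unused).
- The Lilliefors p-value is table-based and saturates at the table edges
  (reported p of 0.001/0.2 are censored values).
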