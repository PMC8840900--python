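# Methods

## Model

The package models point-count biomass with a univariate dynamic species
distribution model of the "spatial Gompertz" family. Observed biomass
`b_i` in sample `i` is gamma-distributed with mean `a·d(s_i, t_i)`, where
`a` is the sampled area (default 0.031 km², the circular area assumed to
contain the vast majority of detections; it only scales the density units)
and `d(s,t)` is the expected density (g/km²) at the nearest spatial knot.
The log-linked predictor is

    log d(s,t) = β(t) + ω(s) + ε(s,t) + γ₁ tit + γ₂ tit² + γ₃ PC [+ γ₄ control]

`ω` is a static Gaussian random field over knots with covariance `σω² R`;
`ε` follows a first-order autoregression over years with Matérn-correlated
innovations, which makes log-density mean-reverting (Gompertz density
dependence) with spatially correlated process error. `R` uses the Matérn
correlation with smoothness fixed at ν = 1, `R_jk = (κ d_jk) K₁(κ d_jk)`,
where the decorrelation range is about `√8/κ`. Geometric anisotropy is
available as a unit-determinant linear coordinate transform parameterized
by a rotation and a log-aspect ratio (both zero = isotropy, the default).

### Parameterization choices

* **Observation dispersion.** The default reads `σm²` as a squared
  coefficient of variation (variance `σm²·μ²`, i.e. gamma shape `1/σm²`).
  A constant-CV gamma is the standard choice for biomass spanning orders of
  magnitude and is what index-standardization software in this model family
  uses; a constant *absolute* variance (`obs_variance="absolute"`) is
  implemented behind a switch for completeness but is not the default —
  with densities ranging over decades a constant absolute variance forces
  near-zero relative noise at high density and is rarely what survey data
  support.
* **Initial condition of ε.** The first year uses the stationary variance
  `σε²/(1−ρε²)·R` by default, so the process is time-homogeneous and the
  AR(1) precision matrix is exactly tridiagonal-Kronecker. An
  `epsilon_init="literal"` option uses `MVN(0, R)` instead.
* **One intercept per year, one dispersion.** `β(t)` is a fixed effect per
  year; `σm²` is a single parameter.
* **Unconstrained transforms.** Variances and κ are optimized on the log
  scale, `ρε = tanh(z)`. 95% CIs use z = 1.959964 throughout (two-sided
  Wald), and "significant" means the closed CI excludes zero.

### Estimation

The marginal likelihood of the fixed effects integrates out `(ω, ε)` with
a Laplace approximation. The inner problem is solved by full Newton steps
with backtracking; the inner Hessian has a block-arrow structure (ε blocks
tridiagonal in time, ω coupled to every year through a diagonal block) and
is factorized by a block Cholesky whose fill-in is confined to the ω row,
giving solves and the log-determinant in O(T·x³). Inner convergence
requires a gradient max-norm below 1e-8 scaled by the curvature magnitude
(the scaling matters when a variance component collapses: smaller gradients
are then unattainable in double precision, while the value error stays
quadratic in the gradient residual).

The outer gradient is computed exactly via the implicit-function theorem:
the observation part of the inner Hessian is a sum of rank-one terms, so
every trace reduces to a Takahashi-style selected inverse on the factor's
fill pattern. The analytic path covers the default model forms (gamma-CV or
lognormal, stationary initial condition, isotropy, ≥ 2 years); other forms
fall back to finite differences. Outer optimization is L-BFGS-B with wide
safety-rail bounds on the transformed scales; non-convergence triggers up
to three seeded restarts before a fit is flagged `converged=False` (such
fits are returned, not raised, because the control-group workflow screens
them out). SEs come from a central-difference Hessian of the marginal nll
over the exact gradient; variance parameters that collapsed to the boundary
(log-variance < −12) are held fixed when inverting, and parameters they
render unidentified (ρε without σε², κ without any field variance) get NaN
SEs rather than spurious ones. AIC counts every outer parameter.

Model selection between the linear and quadratic indicator terms keeps the
quadratic only if its AIC is strictly lower *and* γ₂'s 95% CI excludes
zero. A trimming utility removes samples below the 2.5% or above the 97.5%
biomass quantile (linear-interpolation quantiles) for the
extreme-observation sensitivity refit.

### Knots

Spatial knots equal the unique sample locations when `x` matches their
count; otherwise they are seeded k-means centers of the unique locations
(the knot-placement algorithm for sub-sampled meshes is not prescribed by
the model; k-means is the conventional choice in this model family).
Samples inherit the fields of their nearest knot, ties broken toward the
lowest knot index. Coordinates must arrive in a projected planar system in
km; no CRS handling is done.

## Survey ingestion and covariates

Counts arrive as delimited text with a column-mapping dialect. Two census
conventions are supported: pair counts (doubled to individuals, applying
the doubling uniformly to all observation categories) and individual counts
over one or two within-season periods (summed to one annual record).
Duplicate raw rows are summed with a logged warning rather than rejected —
field files often split one species across lines. Raptors, grouse, waders
and waterfowl (poorly sampled by point counts) and non-forest species are
excluded via trait flags. Biomass is count × species body mass; each
point-year yields one sample with indicator (titmouse), target and optional
control biomass. Total biomass is conserved exactly through the split.

Climate screening drops site-years in which any month's within-radius cell
range exceeds 50 mm precipitation or 11 °C (strict inequalities; boundary
values retained). Annual summaries are the sum of monthly mean
precipitation and the mean of monthly mean temperature. The productivity
index is the principal component (correlation-matrix PCA on the
standardized pair) that loads positively on both variables, sign-flipping a
both-negative component; at an exact zero-correlation tie, component 1 is
used with a warning. Habitat classes merge habitats of similar
Shannon–Wiener entropy within structural groups; the merging tolerance is
configurable (default 0.1 nat — no quantitative rule exists for
"similar", so the tolerance is a config knob, not an inference).
Covariates are standardized (mean 0, SD 1, denominator n−1) pooled across
all site-years of the analysis subset and before zero-sample removal, so
that candidate models compared by AIC see identical covariates; the squared
indicator is standardize(tit), squared, then standardized again, keeping
both terms on an SD scale. Zero-response samples are removed before any
gamma fit.

## Control-group benchmark

Random groups of six non-titmouse forest species are drawn uniformly
without replacement within a group (groups may repeat across draws; draws
are uniform, not abundance-weighted). For each group the response excludes
titmice and the group's species, zero-response point-years are dropped, and
the linear model is refitted with the group's standardized biomass as the
covariate (γ₄). Each converged fit is classified: `not_significant` if the
γ₄ CI encompasses zero (closed interval; this test takes precedence),
otherwise `stronger`/`weaker` if the CI excludes the titmouse point
estimate γ₁ from the *linear* titmouse model, else `not_different`.
Summaries report proportions among significant fits only, with
zero-denominator entries flagged as missing rather than divided.

## Synthetic data

The generator draws surveys with exactly the model's structure: uniform
site locations on a square domain, ω and ε by Cholesky factorization of
their stated laws, standardized covariates (right-skewed lognormal raw
indicator biomass; standard-normal PC), and gamma (or lognormal)
observations around `a·d`. Default truth is the France-scale fit of this
model family: γ₁ = 0.198, γ₂ = −0.030, γ₃ = 0.005, β ≈ 10.25,
σω = 0.641, σε = 0.295. Two parameters have no reported value and were
fixed once at field-plausible levels: ρε = 0.5 (moderate interannual
persistence) and σm² = 0.4 (CV ≈ 0.63 for point-count biomass).
κ = 0.02/km puts the decorrelation range near 140 km on a 500-km domain.

A multispecies layer converts samples into species-level Poisson count
records so the ingestion path can be exercised end to end. When the layer
is on, titmouse counts are drawn *first* (Poisson around a latent
intensity) and the indicator covariate is defined from the resulting
biomass, so re-ingesting the records reproduces the generating covariate
exactly and the ingest-then-fit path recovers the same truth as fitting
the directly simulated samples. Forest species receive noisy shares of the
sample biomass (lognormal intensity mixing, SD 0.6 on the log scale, mean
preserved). Two caveats follow. First, species counts are a
moment-matched stand-in — no detectability, phenology or species
interactions — so passing tests say nothing about those features of real
surveys. Second, because every forest species' counts are by construction
a share of total biomass while the indicator is an exogenous covariate,
random control groups track the response more tightly than any real
species subset would; the desk-scale benchmark therefore exercises the
machinery, and the *calibrated* check of the γ₄ test is the pure-noise
control experiment (significance rate ≈ 5%).

## Problem sizes and checks

The statistical acceptance checks run at desk scale, chosen to be
informative per CPU-minute: parameter recovery uses 50 replicates of a
100-knot, 13-year, ~1300-sample survey (bias of γ₁–γ₃ and 95% CI
coverage); the null calibration uses 300 draws of a 50-knot, 8-year
survey. The analysis scripts use an 80-site, 10-year survey and 40 control
draws. Matérn values are checked against an integral-representation Bessel
oracle to 1e-8; the Laplace marginal is checked against the closed-form
linear-Gaussian marginal (1e-6, where Laplace is exact) and against
adaptive quadrature on a 1-knot gamma toy with 1000 observations (1e-4;
the Laplace error of the log-marginal shrinks as O(1/n), and at n = 1000
it is ≈ 3e-5).

## Known limitations

* Dense knot algebra: exact at x ≤ ~1000 knots; a sparse SPDE-precision
  mesh would be the scalable extension.
* No detectability or distance-sampling correction (the surveys use
  unlimited-distance raw counts), no flock-to-pair re-derivation (assumed
  applied upstream in deposited data), no GIS raster extraction (climate
  arrives as pre-extracted cell tables).
* No bias correction of nonlinear derived quantities, no forecasting
  beyond observed years, no joint-species factor structure.
* Wald CIs throughout; profile intervals for variance parameters near
  boundaries would be more accurate but are not implemented.
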