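# Methods

`gibbonascr` estimates the density and abundance of duetting gibbon
groups from fixed listening-post surveys using acoustic spatial
capture-recapture (ASCR).  This note records the model, its assumptions,
the numerical choices, and what the synthetic-data experiments do and do
not demonstrate.

## The model

**State process.**  Locations of groups *calling on a given day* are a
realisation of an inhomogeneous Poisson point process with intensity

    log D(s) = β₀ + β₁x₁(s) + β₂x₂(s) + …   [groups / km², log link]

where the x_j are spatial covariates measured on a habitat mask (a fine
regular grid).  The expected number of daily calling groups over a
region V is TCG = ∫_V D(s) ds, computed as the Riemann sum
Σ_m D(s_m)·a over mask cells of area a.  Forest type enters as a
categorical term with evergreen forest as baseline and two dummy
coefficients (semi-evergreen; non-forest/deciduous/bamboo/other).
Continuous covariates are z-standardized over the fitting masks before
entering the linear predictor; the (mean, sd) pairs are stored in the
fit so predictions onto other masks apply the identical scaling.  The
scaling choice is ours: covariate effects are reported per SD of the
covariate on the fitting region.

**Detection process.**  A post at t detects a group calling at s
independently with probability given by the hazard half-normal form

    g(d) = 1 − exp(−λ₀ exp(−d²/2σ²)),   d = ‖s − t‖,

chosen because it has a "shoulder": for large λ₀ detection stays at
probability ≈ 1 out to an appreciable distance, as expected for loud,
minutes-long duets.  The plain half-normal g₀·exp(−d²/2σ²) is available
for comparison.  Observed bearings are modelled as von Mises around the
true post-to-group direction with concentration κ (κ = 0: bearings
uninformative; κ = 30 ≈ 10° SD).  One κ is shared across posts, sites
and days, and is estimated jointly with the other parameters.

**Likelihood.**  Days are independent occasions; the quantity modelled
is the density of groups calling on a given day, so a group calling on
two days contributes two capture histories and no cross-day identity is
needed for this part of the analysis.  Latent locations are integrated
over each site's local mask.  With active posts T_ij on occasion (i,j),
p·(s) = 1 − Π_l (1 − g(d(s,t_l))), and Λ_ij = a Σ_s D(s) p·(s), the
occasion contributes the unconditional (Poisson) SCR form

    −Λ_ij + Σ_k log[ a Σ_s D(s) Π_l g^ω (1−g)^{1−ω} Π_{l:ω=1} vM(θ_obs | θ(s,t_l); κ) ].

Posts inactive on a day (the post tables carry per-post active-day
sets) are dropped from that day's products and from p·(s) — the
standard effort correction.

**Calling probability and abundance.**  Only groups that call can be
detected, so TCG understates the number of groups.  The daily calling
probability p is estimated from calibration groups ever detected within
500 m of a post (categories `<500 m` and `500 m`): such groups are
detected essentially whenever they call and can be identified across
days, so their per-day calling record is observed — except that a group
silent on all n_k days never enters the sample.  Hence
y_k ~ zero-truncated Binomial(n_k, p), maximized in p; n_k is the
number of distinct survey days on which at least one of the group's
detecting posts was active.  Groups with n_k = 1 are uninformative
under truncation and are dropped with a warning.  Then D_g(s) = D(s)/p
and TGG = TCG/p.  p(m) = 1 − (1−p)^m gives the proportion of groups
expected to call at least once in m days.  Calling is assumed
independent across days and homogeneous across groups and days; the
package encodes this assumption, it does not test it.

## Estimation and numerics

* Working scale: identity for β, log for λ₀, σ, κ.  L-BFGS-B
  quasi-Newton with up to three jittered restarts; non-convergence is an
  error, never silently reported estimates.
* Starting values: β₀ from a naive detected-count density, σ at half
  the 500 m post spacing, λ₀ = 2, κ = 10.
* Variance: inverse observed information from a central finite-difference
  Hessian at the MLE (relative step 5·10⁻⁴); Wald intervals on the
  working scale, hence log-normal intervals for λ₀, σ, κ.
* Detection probabilities are evaluated through the exact log-survival
  −λ₀e^{−d²/2σ²} and `expm1`, keeping full relative precision in both
  tails (g ≈ 0 and g ≈ 1); log I₀(κ) uses the exponentially scaled
  Bessel function, stable for large κ.
* Occasion integrands are evaluated in log space with `logsumexp`.
* Bearing quadrature on coarse masks: the von Mises factor varies on the
  angular scale 1/√κ (≈ 10° at κ = 30), which at typical detection
  distances is comparable to a 250 m grid cell, so the plain midpoint
  rule attenuates κ̂ (we measured ≈ −20% at 250 m spacing).  The fitter
  therefore offers a cell-averaged bearing kernel
  (`bearing_cell_blur`): per capture history, the joint product of von
  Mises terms is averaged over a 3 × 3 subgrid of each cell while the
  smooth density and detection factors stay at the cell centre.  The
  average must be joint — averaging each bearing factor separately lets
  each bearing pick its own within-cell location and biases κ̂ upward.
  The correction converges to the plain likelihood as spacing → 0; it is
  off by default (the documented likelihood contract is the midpoint
  rule) and on in the recovery experiments, which deliberately run on
  coarse masks.  With it, κ̂'s bias at 250 m spacing is ≈ +1%.
* AIC = 2k − 2ℓ; all-subsets selection over a pool of six covariates
  (2⁶ = 64 models; forest counts as one variable, two parameters); ties
  below 10⁻⁶ break toward fewer parameters.  The likelihood-ratio test
  for the forest term uses χ² with 2 df.
* The calling-probability CI is profile likelihood (the 1.92 log-lik
  drop), found by bisection; the MLE itself by bounded scalar
  minimisation to 10⁻¹⁰.
* Abundance intervals: parametric bootstrap, default B = 300 —
  parameter vectors drawn from MVN(MLE, vcov) on the working scale, TCG
  recomputed per draw over the prediction mask; independently y*_k are
  simulated from the fitted zero-truncated binomial and p re-estimated;
  TGG* = TCG*/p*.  Percentile 2.5/97.5 intervals; SE is the replicate
  SD; CV = SE/point.  A vcov that is not positive semidefinite is an
  error.  (A full simulate-and-refit bootstrap would be preferable at
  scale but MVN resampling is the tractable default on a desktop.)

## Masks and covariates

Fitting uses per-site local masks: grid points within a buffer (default
4 km, spacing 100 m in `local_mask`; the simulation experiments use
3 km / 250 m) of the site's posts.  At the fitted detection scale
g(d) < 10⁻³ beyond ≈ 2.4 km, so a 3–4 km buffer loses nothing.
Prediction uses a park-wide mask over the boundary polygon.  Distance
covariates are exact Euclidean nearest-feature distances (point sets
via a k-d tree, lines/polygons via geometry distance) rather than
distances from a 30 m rasterized layer; a `RasterGrid` with nearest-cell
sampling covers raster covariates and can reproduce a rasterized mode.
All coordinates are assumed to share one metric projection.  All
in-boundary points are treated as habitat.  A covariate observed only
near posts (distance to logged trees, mapped only within 2 km of sites)
cannot be predicted park-wide; asking for park-wide TCG under such a
model raises a coverage error, and the best model without that
covariate is the one to extrapolate.

## Group identification (survey preparation)

Raw detections are filtered: same-day repeat duets are dropped; male
solo calls are dropped unless a retained duet at another post of the
same site-day overlaps it in time (≥ 1 min) and implies a location
within 500 m — evidence the "solo" was a distant duet.  Same-day
detections are merged greedily in chronological order into groups when
implied locations (bearing + representative category distance; 250 m
for the `<500 m` bin midpoint, else the category label) are within
500 m and call windows overlap by ≥ 1 min (or nest).  Cross-day
identity — needed only for the calling-probability calibration — uses
nearest same-site centroid within 500 m, each persistent group matched
at most once per day.  Field practice resolves ambiguous cases with
expert judgement on duet features; no published decision rule exists,
so these features are carried as metadata but not used algorithmically.
The greedy rule is deterministic under row shuffling (processing is
sorted by day, start time, post, bearing) and recovers the true
grouping exactly when groups are well separated; at nearest-neighbour
spacings comparable to the 500 m merge radius it will sometimes merge
distinct groups, which is a documented limitation, not an estimator
property.

## The synthetic generator and what the experiments show

`simulate` reproduces the design (3 posts / 500 m / 3 days,
configurable dropout via per-post active days) on independent per-site
landscape windows (posts + 3.5 km): continuous covariates are smoothed
Gaussian white-noise fields standardized to mean 0, SD 1; forest
classes come from quantile-thresholding an auxiliary field (defaults
0.5/0.8 → 50/30/20%).  Groups are placed by thinning against the
piecewise-constant D_g = D/p; calling is Bernoulli(p) per day; detection
Bernoulli(g(d)) per post; bearings are true direction + von Mises
error; distance categories bin the true distance at 500/750/1250/1750 m
(an abstraction of observer rounding — no field error model for the
categories exists).  Group locations are fixed across days, matching
the home-range-centre view; per-day jitter is available and defaults to
0 m.

`parameter_recovery_experiment` runs simulate → prepare → fit →
calling-probability, by default building capture histories from the
generator's known identities.  This isolates what it is meant to
measure — calibration of the *estimator* — from the group-assignment
heuristic, which is validated separately and which no automatic rule
can make error-free at realistic densities (truth D_g = 1.5 groups/km²
puts typical nearest neighbours near the 500 m merge radius).
Experiment defaults (40 sites, 50 replicates, 250 m mask spacing, 3 km
fitting buffer, truth D_g = 1.5, p = 0.65, λ₀ = 50, σ = 500 m, κ = 30)
keep a full run within minutes on one CPU.

Passing recovery experiments show the estimator is approximately
unbiased with near-nominal interval coverage *under the generating
model*: real surveys add group misidentification, distance-category
error, observer bearing bias, temporally correlated calling and
covariate measurement error, none of which the generator emulates.
One genuine model-truth mismatch is retained deliberately: because
group locations are fixed across days while the likelihood treats days
as independent Poisson realisations, detected counts are mildly
overdispersed relative to the model, so density-intercept intervals
can run slightly below nominal coverage.  This mirrors the field
situation the model is applied to.

## Known limitations

* No conditional-likelihood SCR, Bayesian fitting, interaction or
  spline terms, or time-of-day call-rate modelling.
* Heterogeneity in calling probability (weather, group identity) is not
  modelled.
* Distance-category observation error is not modelled; categories are
  used only for group discrimination and calibration-group selection,
  never in the likelihood.
* The group-assignment heuristic is a documented stand-in for expert
  judgement; its merge radius and minimum overlap are configurable.
* Shapefile/GeoTIFF I/O is out of scope; boundaries come from GeoJSON
  or shapely geometries, rasters from in-memory grids, tables from CSV.
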