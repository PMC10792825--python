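# Methods

## Scope

The package is a desk-scale re-implementation of a weather-dependent
habitat-selection analysis for alpine ungulates. Because the original GPS
data are not publicly deposited, the package ships its own generative
module; every downstream stage consumes either synthetic inputs or user
data in the same shapes (fixes CSV, rasters, hourly station weather CSV).

## Synthetic landscape

Elevation is white Gaussian noise low-pass filtered with a Gaussian kernel
(`smoothness`, in cells; default 8) and rescaled exactly to the configured
range (default 1380–3173 m, an alpine national-park envelope). Slope and
aspect come from Horn's 3×3 finite-difference stencil with edge
replication, the algorithm behind the common GIS surface tools; aspect is
the downslope direction, degrees clockwise from north. Flat cells (zero
gradient) have undefined aspect and get northness = eastness = 0, a
neutral value that biases no exposure. Tree cover density is built from a
standardized copy of elevation mixed with residualized smooth noise so
that the in-sample correlation with elevation equals the target exactly
(default −0.6, matching the elevation–forest anticorrelation typical of
the tree-line gradient); the mix is mapped linearly to [0, 100] %, which
preserves the correlation. Three epoch layers (2012/2015/2018) differ by
small smoothed perturbations (SD 1.5 %, clipped).

Rasters are written as single-band float32 TIFF with a JSON sidecar
(origin, cell size, nodata) or as plain-text ESRI ASCII grid. No CRS
machinery is included: coordinates are projected metres by contract.

## Synthetic weather

A single virtual station (weather is spatially constant). Hourly
temperature = seasonal mean (10 °C summer, −8 °C winter by default,
appropriate for ~2000 m a.s.l.) + a slow seasonal drift + a diurnal
harmonic peaking at 14:00 + AR(1) noise (φ = 0.8). Hourly maximum wind is
coupled to the standardized temperature anomaly with latent correlation
0.45 (the observed alpine-station value is ≈ 0.4–0.5) and clipped at 0.
Precipitation per 3-h bin is zero with probability 0.8, else gamma
(shape 0.6, scale 3 mm) — zero-skewed, as alpine precipitation records
are. Snow depth is a daily (05:00) bounded random walk ≥ 0 in winter and
identically zero in summer. Precipitation is attached to the *end* of its
3-h bin; lookups map a timestamp to the bin containing it. Snow lookups
return the same calendar day's 05:00 reading.

## Trajectory simulation

The generative scheme is the standard SSF-consistent one: at each 4-h tick
a finite candidate set (default 200) of endpoints is drawn from the
movement kernel — gamma step lengths (default shape 1, scale 185 m, i.e.
median ≈ 128 m, a realistic chamois summer median) and uniform turning
angles — and one candidate is chosen with probability
softmax(x'β). As the candidate set grows this converges to the continuous
step-selection density. Candidates falling off the raster are redrawn
(bounded retries), and start points are drawn from the interior of the
extent. Truth coefficients live on the *generator's* standardized scale:
habitat moments over the whole raster, weather moments over the simulated
window. Individual heterogeneity enters as random slopes drawn once per
individual. The observational study the design mirrors provides no
generative model; all simulator distributions are package choices and are
labelled as such.

What the generator deliberately does not emulate: GPS measurement error
(beyond what the position screen exercises), spatially varying weather,
vegetation phenology, home-range attraction, and behavioural modes.
Passing tests therefore demonstrate estimator correctness under the
model's own assumptions, not robustness to the many ways field data
violate them.

## Step preparation

* Position screen: a fix is deleted when the implied speed both into and
  out of it exceeds a ceiling (default 5 km/h, chamois-plausible).
  Endpoints and two-fix tracks are never removed (the rule needs both
  legs). The published screen the original analysis cites has no published
  parameters, so this documented round-trip rule replaces it.
* Steps are formed only between consecutive fixes 4 h ± 30 min apart
  (collar-jitter tolerance); larger gaps split the track into bursts and
  no step or turning angle crosses a burst boundary.
* The tentative gamma step-length distribution is fitted per individual by
  maximum likelihood: the shape solves log k − ψ(k) = log(mean) −
  mean(log) by Newton from the usual moment start; scale = mean/shape.
  Zero lengths are floored at 1 m (gamma support is positive).
* 10 random steps per realized step (strata of 11), lengths from the
  individual's tentative gamma, turning angles uniform relative to the
  previous step's direction. Off-raster draws are redrawn; a stratum whose
  draws cannot be placed is dropped and counted.
* Annotation: raster values at the cell containing each endpoint; tree
  cover from the epoch nearest the fix year, ties towards the earlier
  epoch (deterministic); weather at the step *end* time — the covariates
  describe conditions where the animal chose to be; day/night at end time
  from sunrise/sunset at solar zenith 90.833° (refraction + solar
  semidiameter), computed from the NOAA solar equations iterated at the
  event time. All timestamps are treated as UTC.
* Seasons: summer = June–October, winter = December–April; May and
  November excluded. The completeness rule keeps an individual only with
  ≥ 80 % of the theoretically possible positions (season days × 6
  fixes/day); it applies to full-season field data and is off by default
  for short synthetic windows.
* Standardization: all continuous covariates (including step length) are
  centred and scaled over the pooled used + available records of the
  season; the moments are stored for back-conversion. The day flag stays
  0/1. Snow is a winter-only covariate (it is identically zero in the
  summer generator, and a constant column cannot be standardized).

## The selection model

The full-model grammar: habitat mains (elevation, slope, tcd, northness,
eastness) plus step length; interactions of elevation and tcd with every
weather variable and day/night; slope with precipitation, wind, snow and
day/night but not temperature; northness only with temperature; eastness
with nothing; plus tcd × slope. Summer has 19 fixed-effect columns, winter
22 (snow terms). Stratum-constant modifiers are rejected as lone fixed
effects — they are unidentifiable in a conditional likelihood.

Three fitting routes:

1. `fit_conditional_logistic` — Newton–Raphson from β = 0 on the exact
   per-stratum softmax likelihood; covariance from the inverse observed
   information. Separation is detected by a diverging coefficient norm and
   flagged. Convergence: gradient norm < 1e-6 and relative log-likelihood
   change < 1e-9, with a numerical-floor clause (change < 1e-13 and
   gradient < 1e-3) for large samples where double precision saturates
   first.
2. `fit_poisson_trick` — the Poisson reformulation with one intercept per
   stratum under a normal penalty of variance 10^6 (not estimated, not
   counted in AIC). Intercepts are profiled inside each Newton step; the
   slope Hessian uses the exact Schur complement. At infinite variance the
   profiled intercepts equal −log Σ exp(η) and the two log-likelihoods
   differ by exactly −N (each stratum's fitted Poisson means sum to 1);
   at 10^6 the difference from −N is O(N/V).
3. `fit_mixed_issf` — the mixed model. Route taken: stratum intercepts are
   profiled out exactly (the conditional likelihood), individual random
   slopes on habitat mains (diagonal covariance) are integrated by a
   Laplace approximation per individual. For fixed variances the joint
   mode over (β, b) is found by full Newton (the Hessian is assembled
   block-wise per individual); the marginal likelihood is maximized over
   log-SDs by Nelder–Mead with warm-started inner solves. β is evaluated
   at the joint mode (the dependence of the Laplace determinant on β is
   ignored, the usual approximation). A variance reaching the lower bound
   (log-SD −6) is reported via a flag, not an error. Random slopes apply
   to habitat mains only; AIC = −2·(Laplace log-lik) + 2·(fixed effects +
   estimated variance components).

The equivalence of routes 1 and 2, the zero-variance limit of route 3,
agreement with `statsmodels` ConditionalLogit and with `glmmTMB`'s Poisson
formulation (the estimator's reference software) are all under test.

## Backward AIC

Every removable term is dropped in turn each round; the lowest-AIC
candidate replaces the incumbent when it improves it, otherwise selection
stops. Removable: interactions always; a habitat main only when absent
from all retained interactions (marginality — so no accepted model
contains an interaction whose main is gone); step length never (it is a
movement-kernel adjustment). Ties break towards fewer parameters, then
lexicographic term order, making the trace deterministic. Candidates that
fail to converge are skipped with a warning. Near-ties (ΔAIC < 2 against
the accepted model) are recorded in the trace.

## Relative-selection curves

f_u/f_a(x) = exp(η(x, moderators) − η(x_ref, moderators)) with the focal
covariate on its original units (via the stored standardization), other
habitat terms at the season mean (z = 0), and moderators fixed at chosen
levels — by default the seasonal minimum/mean/maximum, or quantile-capped
levels for zero-skewed covariates such as precipitation. The 95 % band is
the delta method on the linear-predictor contrast (normal quantile
1.959964) using the fixed-effect covariance only: population-level curves
that ignore random-slope deviations. The curve is exactly 1 at the
reference and is invariant to affine changes of the focal covariate's
units. No statement is made that this is the original analysis's CI
method (which is unreported); it is this package's documented choice.

## Packaged experiments and problem sizes

* Parameter recovery: 200 replicates of 30 individuals × 200 steps
  (≈ 6,000 strata each), truth with five nonzero terms including two
  weather × habitat interactions of magnitude 0.3 and zero random-slope
  SDs, fitted with the full 19-term summer model by conditional logistic
  regression. Fitted coefficients are mapped onto the generator's
  standardized scale by exact affine algebra (the pipeline's pooled-strata
  moments differ from the generator's raster/window moments; both
  z-transforms are affine, so the conversion is a matrix identity, not an
  approximation). Reported: per-term bias, RMSE and 95 % CI coverage.
* Random-slope recovery is checked separately (30 individuals × 200
  strata, SD 0.5 on one habitat term) with the mixed fitter.
* Selection experiment: 20 replicates of 15 individuals × 210 steps
  (≈ 3,000 strata), strong effects on all terms except a true-zero
  precipitation × slope, conditional-logistic fits inside backward AIC.
  Reported: removal rate of the zero term and AIC-path monotonicity.
* `scripts/acceptance.py` runs reduced versions (60 and 10 replicates) to
  stay within a few minutes on one CPU; the full sizes run in the test
  suite.

## Numerical and design notes

* Seeds: one global seed is fanned out to per-stage child seeds via
  `numpy.random.SeedSequence.spawn`; every generator is a pure function of
  (config, seed) and the pipeline is byte-reproducible.
* The day/night boundary is half-open (sunrise ≤ t < sunset).
* Wald stars at p ≤ 0.05 / 0.01 / 0.001, boundaries inclusive.
* The tentative gamma is fitted per individual over the pooled season
  (not per individual-season); the model includes linear step length only
  (no log-length or cos-turn adjustment terms), matching the reported
  model structure the package reproduces; both choices are config-visible
  switches in spirit — the kernel and the extra columns can be supplied by
  editing the prepared strata.

## Known limitations

* The Laplace mixed fit profiles β at the joint mode; for very small
  individual counts the variance estimates are biased low, the familiar
  Laplace behaviour.
* The simulator's finite candidate set (200) makes the generative process
  an approximation of the continuous SSF; recovery tests bound the
  residual bias (< 0.01 on coefficients of 0.3) rather than eliminating
  it.
* The curves module reports population-level uncertainty only.
* No robust/sandwich standard errors, no correlated random effects, no
  forward or all-subsets selection.
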