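# Methods

## The selection model

Telemetry is reduced to discrete choice sets: every fix of individual
*j* at time *t* contributes one multinomial outcome among *I* = 1 +
`n_available` alternatives — the used location plus `n_available`
(default 5) points sampled uniformly on the disk of the availability
radius centred at the used location. A 5:1 available-to-used ratio
balances computational cost against the variance of the availability
sample; alternatives falling off the raster are resampled so the ratio
is exact. Locations used on several occasions get independent
availability samples each time.

The availability radius is the mean over individuals of the maximum
straight-line displacement achievable in 24 h. When the tracking
interval exceeds 24 h (the simulated default is 54.5 h), no fix pair
falls inside a day, and an individual's maximum consecutive-step
displacement is pro-rated by 24 h / (its mean step duration). This
linear pro-rating is a modelling choice, not an estimate of the true
24-h kernel; it errs conservative (shorter radius) for long intervals.
A fixed radius can be supplied instead (`analysis.availability_radius`).

Selection follows a mixed conditional logit. Utility is `U_ij = β_j'
x_ij`; choice probability is the within-set softmax ψ_ij. Because ψ is
invariant to anything constant within a choice set, covariates that do
not vary among alternatives (day of year, intercepts) enter only through
interactions. Individual coefficients are exchangeable draws from
`β_jk ~ N(μ_k, σ_k²)`; μ_k and σ_k are the population-level estimands.
Priors: `μ_k ~ N(0, 100)`, `σ_k ~ U(0, 10)` — vague on the z-score
scale of the covariates.

### Covariates

At each (point, time): buffer mean and population SD of canopy cover
(vegetation > 3 m), buffer mean of understory cover (1–3 m), buffer
mean temperature, its centred square, and buffer SD of temperature. The
buffer takes all raster cells whose centres lie within 15 m of the
point: 7.07 cells on average on a 10-m grid (π·15²/100), 9 cells when
the point sits exactly on a cell centre. The population (divide-by-n)
SD convention is used throughout; with ~7 cells the n vs n−1 choice is
material and must be fixed once.

All covariates are z-scored over the pooled used + available rows of a
dataset, and the fitted standardization is stored for prediction-time
reuse. Interactions multiply the standardized main effect by
standardized day of year (both z-scored before the product).

The quadratic temperature term is built as the **centred square**
`(T − T̄)²` (T̄ = pooled mean temperature) and then z-scored. Over a
single April–September season all temperatures are positive, so raw T
and T² are nearly collinear and the pair is poorly identified — the
classic argument for centring before forming polynomial terms. The
centred basis spans exactly the same {1, T, T²} model space (the change
is a linear reparameterization whose constant part cancels within
choice sets) but leaves the linear and quadratic columns close to
orthogonal, so both coefficients are recoverable.

### Candidate models

Seven nested specifications: null; habitat only (canopy mean, canopy
SD, understory); temperature only (T, T², T SD); habitat + temperature;
habitat × season; temperature × season; and the full habitat +
temperature × season model (10 terms). Seasonal (day-of-year)
interactions are attached to canopy mean, canopy SD, understory and
temperature SD but **not** to the linear and quadratic temperature
terms, on the assumption that the physiologically preferred temperature
itself is seasonally constant; only the value of thermal heterogeneity
shifts with season.

## Sampler

Metropolis-within-Gibbs, one iteration being:

1. each β_j updated by a joint K-dimensional random-walk Metropolis
   step against the log-likelihood of j's choice sets plus its
   N(μ, σ²) prior (all individuals proposed and accepted in parallel);
2. each μ_k drawn from its conjugate normal full conditional;
3. each σ_k updated by random-walk Metropolis on (0, 10) against the
   normal likelihood of the β·k column (proposals outside the support
   rejected, which preserves the uniform prior exactly).

Proposal scales adapt every 50 iterations toward ~0.3 acceptance during
burn-in only, then freeze, so the retained chain is a valid
fixed-kernel Markov chain. Chains initialize over-dispersed
(μ ~ N(0,1), σ ~ U(0.5,2), β_j ~ N(μ, σ²)) with bounded retries should
the starting likelihood be non-finite. The default schedule (3 chains ×
25,000 iterations, 10,000 burn-in, thin 15) retains exactly 3,000
draws. Convergence is monitored by Gelman–Rubin R̂ with the usual 1.1
warning level. The sex-grouped variant duplicates (μ, σ) per sex and is
otherwise the identical sampler.

## Model comparison

WAIC uses one choice set as the pointwise unit (each set is one
exchangeable multinomial contribution): `lppd = Σ_i log mean_s
exp(ll_is)` (computed via logsumexp), `p_waic = Σ_i var_s(ll_is)` with
the n−1 draw-variance, `WAIC = −2(lppd − p_waic)`. The null model is
scored analytically (`lppd = −Σ ln I_i`, `p_waic = 0`).

Estrella's R², `1 − (L_fit/L_0)^(−(2/n)L_0)`, uses the log-likelihood at
the posterior means of the individual β_j as the plug-in (the posterior
mean deviance is a noted alternative), L_0 = random choice, n = number
of choice sets. It is 0 exactly when the model predicts at random and
→1 for perfect prediction.

## Synthetic data generator

The generator defines the study conditions the package is tested under.

- **Landscape**: a correlated Gaussian field (smoothed white noise,
  correlation length default 60 m) thresholded at its empirical
  quantile so a chosen fraction of cells (default 0.6) is forest
  (canopy ≈ 85%) and the rest field (≈ 5%), plus within-class texture
  and one-cell smoothing that produces soft forest–field edges.
  Understory is an independent correlated field rescaled to [0, 100].
  10-m cells, matching the native grain of LiDAR vegetation rasters.
- **Temperature**: `T(p, t) = mean + A_s·cos-cycle(day of year, peak
  172) + A_d·(1 − d·canopy(p)/100)·cos-cycle(hour, peak 15) + ε(p)`
  with defaults mean 20 °C, seasonal amplitude 8 °C, diurnal amplitude
  6 °C, canopy damping 0.5 and a frozen correlated spatial anomaly
  (SD 1 °C, 30 m) — magnitudes typical of temperate-forest
  microclimate, chosen once. This is a parametric stand-in exposing the
  same query interface `T(point, datetime)` as a fitted downscaled
  temperature model; it is *not* a physical microclimate model (no
  weather, no elevation, no radiation balance).
- **Telemetry**: each of `n_individuals` (default 53) draws β_j from
  the configured population truth, starts at a uniform random location,
  and at every step (default 54.5 h, April–September) picks among
  `candidates_per_step` (default 20) uniform points in its availability
  disk with softmax probabilities. The generating coefficients act on
  covariates z-scored by a fixed *reference standardization* estimated
  from 3,000 uniform (point, time) samples, so the truth lives on the
  same scale the fitted model uses (global location shifts cancel
  within sets; only scale alignment matters, and both pools have nearly
  identical spreads). The candidate count is deliberately richer than
  the fitted 5:1 availability sample — uniform subsampling of
  alternatives leaves conditional-logit estimation consistent. Sex
  labels alternate by individual index and do not affect behaviour.

What the generator does **not** emulate: GPS measurement error, home
ranges or site fidelity (steps are memoryless), habitat-dependent
movement rates, missed fixes, temporal autocorrelation in temperature
anomalies, and observer effects. Passing recovery tests therefore show
the estimator is correct *for this generating process*, not that field
data meet its assumptions.

## Numerical choices

- Softmax and lppd use max-subtraction / logsumexp; likelihoods are
  exact for finite inputs.
- Buffer membership is a centre-in-disk test; buffers are never empty
  for in-extent points at radius ≥ cell/√2.
- Uniform-disk sampling is rejection from the bounding square
  (area-uniform); off-raster points are resampled.
- Choice sets are built in canonical (individual, time) order, making
  construction independent of input row order.
- Degenerate inputs fail loudly: zero-spread covariates name the
  offending column; out-of-extent queries raise, except used telemetry
  points, which are skipped with a logged count.
- Min–max normalization of use surfaces maps exp(utility) to [0, 1] per
  map (constant maps to 0.5); cells whose buffer leaves the raster are
  masked NaN. "Relative probability of use" therefore compares cells
  within one surface, not across dates.
- Effect curves use a two-alternative contrast against a location held
  at the observed covariate mean, pinning every curve to 0.5 at the
  mean; surfaces default to 12:00 local time.

## Test problem sizes

The automated suite favours small, seeded problems: recovery uses 40
individuals × 80 fixes with a reduced chain schedule (3 × 5,000, burn
2,000, thin 10 — 900 draws), model-selection and sex-difference
replicates use 6–16 individuals with shorter chains, and the full
25,000-iteration schedule is exercised on a toy dataset to verify the
retained-draw bookkeeping. These sizes were chosen so the whole suite
runs in about a minute while keeping Monte-Carlo error far below the
asserted tolerances.

## Known limitations

- The hierarchical covariance is diagonal (independent β_jk given μ, σ);
  correlated random coefficients are not modelled.
- One coverage property is knowingly strict: with well-calibrated 90%
  intervals on 10 sex-difference coefficients, the joint event "every
  interval overlaps zero" holds in only ≈ 0.9¹⁰ ≈ 40–50% of replicate
  datasets, so the suite's strictest sex-null check fails by design of
  the probability involved, while per-parameter calibration is
  confirmed. See the test for details.
- No spatial autocorrelation in choice residuals, no observation-error
  model beyond the 15-m buffer, no movement-kernel weighting of
  availability, and no marginal-likelihood/Bayes-factor machinery.
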