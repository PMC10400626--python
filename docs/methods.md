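# Methods

## The model

`flowimpact` estimates the effect of a policy intervention on a monthly
count series — here the monthly number of sea-crossing attempts on a
migration route, defined as the exact sum

    Y_t = A_t + P_t + D_t

of arrivals, pushbacks to the departure coast, and recorded deaths.  The
analysis is an interrupted time series with a model-based counterfactual:
a Bayesian structural time-series (BSTS) model is fitted to the months
*before* the intervention month τ, then propagated over the post-τ months
to obtain the posterior-predictive distribution of the series had the
intervention not occurred.  Observed minus predicted, per posterior draw,
is the pointwise effect; its running sum is the cumulative effect.

On the log scale (a variance-stabilising `log(Y_t + 1)` transform, since
monthly counts show periods of both rising and falling variance), the
observation equation is

    y_t = Z' α_t + x_t' β + ε_t,      ε_t ~ N(0, σ²)

and the state equation

    α_{t+1} = T α_t + R η_t,          η_t ~ N(0, Q)

with three components:

- **Local linear trend** — level and slope states, each a random walk with
  its own disturbance variance.
- **Seasonal** — a sum-to-zero dummy seasonal of period s = 12 (s − 1
  states; the newest seasonal state equals minus the sum of the previous
  eleven plus noise).  The sum-to-zero constraint keeps the seasonal
  pattern identifiable against the trend.
- **Static sparse regression** — a mean shift `x_t' β` from a wide panel
  of exogenous covariates (economic indices, weather, conflict/disaster
  indicators, air-traffic flows, and their one- to six-month lags).  With
  six lags the design typically has more columns than time points, so β
  carries a spike-and-slab prior: each coefficient is zero with prior
  probability `1 − π_j` and otherwise drawn from a Zellner-style
  conditional Gaussian slab whose precision equals the information in
  `κ` prior observations, `Ω⁻¹ = (κ/n)(w·X'X + (1−w)·diag X'X)` with
  diagonal weight `1 − w = 0.5` so the prior stays proper for p > n.
  σ² has a conjugate inverse-gamma prior worth 0.01 observations with a
  prior guess of half the sample variance of the target (an expected R²
  of one half).

The observation-noise variance is time-constant; regression coefficients
are static.  (Stochastic volatility and dynamic coefficients are out of
scope.)

## Posterior computation

A blocked Gibbs sampler cycles three steps per iteration:

1. **States** — a joint draw of α_{1:T} given variances and β, by the
   mean-correction simulation smoother: simulate an unconditional
   replicate (α⁺, y⁺), smooth the difference series y − y⁺ with a
   zero-mean initial state (the affine constant cancels), add α⁺ back.
   Exact in the linear-Gaussian model.  The underlying Kalman filter uses
   a proper, weakly informative initialisation (level mean = first
   observation, other states 0, variances 10⁶ × the sample variance);
   missing observations skip the update step.
2. **Component variances** — conjugate inverse-gamma draws from the state
   disturbances implied by the sampled path.
3. **Regression** — one spike-and-slab scan: each inclusion indicator γ_j
   is flipped against its conditional posterior odds (conjugate
   normal–inverse-gamma marginal likelihoods, integrating out β and σ²),
   then σ² | γ and β | γ, σ² from closed-form conditionals.  Excluded
   coefficients are exactly zero.

Defaults: 10,000 iterations in the command-line pipeline (2,000 in the
estimator API, adequate for the 60–120-month problems exercised here),
burn-in 10% of the run, prior expected model size 5, slab weight κ = 1.
A single seeded `numpy` generator is threaded through every draw, so a
run is a pure function of (data, configuration, seed).

**Trend variance priors.**  The level and slope disturbance variances get
inverse-gamma priors worth 32 observations with prior standard-deviation
guesses of 0.01·sd(y) (level) and 0.001·sd(y) (slope); the seasonal
disturbance gets 0.01·sd(y).  These are deliberately informative, following
the convention popularised by the widely used R implementations of this
model family: the likelihood is nearly flat along a ridge trading trend
variance against observation noise, and an unrestrained trend both soaks
up variation that belongs to the covariates and makes multi-month
counterfactual forecasts uninformative (slope-drift variance grows like
h³).  A counterfactual design presumes the covariates, not a volatile
trend, explain the medium-run movement.  The prior strength is exposed as
`variance_prior_df`; parameter-recovery experiments that specifically
probe the likelihood's ability to track a volatile trend should lower it
(the test-suite's trend-recovery experiment uses 0.01).

**Prediction.**  For each retained draw the final state is propagated
through the state equation with fresh disturbances, the regression shift
from the *observed* post-period covariates is added (their exogeneity is
what the Granger screen checks), and observation noise is applied.
Count-scale summaries exponentiate each draw before summarising —
never the other way around, which would ignore the Jensen gap.

**Pre-period validation.**  One-step-ahead predictions at the posterior
mean of (variances, β, σ²) give a count-scale MAPE, empirical interval
coverage, and a Ljung–Box portmanteau test on standardized residuals.
The first seasonal cycle plus two months is excluded: under the diffuse
initialisation the filter's early one-step predictions are vacuous.

## Pre/post hygiene

- The month *containing* the intervention start date belongs to the post
  period, even for mid-month starts, so no partially treated month leaks
  into training.
- Covariate standardization uses pre-period statistics only, frozen and
  applied to the post period.
- Mutating post-τ observations provably leaves the fitted posterior
  unchanged (asserted by a test).

Three interventions analysed on one dataset each use only the months
before their own τ for fitting.  Later post-periods overlap later
interventions; the per-intervention results are joint effects of
everything changing from τ onward, not isolated delayed effects.

## Diagnostics

- **Decomposition** — classical centered 2×12 moving-average
  decomposition into trend, seasonal (re-centered to sum to zero) and
  remainder, via `statsmodels.seasonal_decompose`.
- **Breakpoints** — exact dynamic-programming segmentation of a
  mean-shift model (prefix-sum segment costs, minimum segment length 12
  months by default), with the number of breaks chosen by BIC using
  2k + 1 effective parameters.  The DP optimum is verified against
  exhaustive enumeration on instances up to length 40.
- **Granger exogeneity screen** — for each intervention (encoded as a
  0/1 step dummy) and each covariate, an F test of the candidate's lags
  1..m added to the target's own-lag regression,
  F = ((RSS_r − RSS_u)/m)/(RSS_u/(n − k)).  Both series are differenced
  once when an augmented Dickey–Fuller pre-check (level 0.05) fails to
  reject a unit root in the target.  Under exogeneity the flagged
  fraction is close to the test level.

## The synthetic-data generator

No real monthly flow or covariate data can be redistributed, so the
generator emulates their structure with known ground truth:

- latent log-intensity = local linear trend (level sd 0.01, slope sd
  0.001 per month — a level that wanders a percent per month with mild
  slope drift; the covariates, below, carry the medium-run signal) + a
  fixed sum-to-zero 12-month pattern (sd 0.15, matching the strong summer
  seasonality of sea crossings) + sparse covariate effects + step
  intervention effects `log(effect)·1[t ≥ τ]` + log-normal noise (sd
  0.05);
- counts `Y_t ~ Poisson(exp(λ_t))` (or negative binomial with dispersion
  r, Poisson being the r → ∞ limit; or the rounded mean for exact
  fixtures), around a base level of 1,000 crossings per month;
- covariates in three families: AR(1) with coefficient 0.8 (economic
  proxies), annual sinusoids plus noise (weather), sparse non-negative
  spikes (conflict/disaster);
- `Y_t` split multinomially into arrivals/pushbacks/deaths with expected
  shares 90/6/4% — deaths are a small (~4%) share of the total, as in the
  observed series — so the additive identity holds exactly;
- optional binomial thinning of deaths (default rate 0.10 when enabled)
  emulating under-recording of deaths by the registries.

What the generator does **not** emulate: the magnitudes and heavy tails of
the real series, reporting artefacts (effort-dependent detection of
deaths, backfilled records), covariates that respond to the interventions,
and effects that phase in gradually rather than as a step.  Passing tests
therefore demonstrate that the machinery is correct and calibrated under
its own assumptions, not that those assumptions hold for any real route.

## Study conditions used by the tests and the acceptance script

- **Coverage**: 50 no-effect replicates (60 training months, 12 held-out
  months, 10 candidate covariates of which 5 active, 2,000 iterations):
  pointwise 95% predictive intervals cover held-out truth at ≈95%.  The
  bands run a point or two conservative (observed ~97% across seeds):
  the observation-variance posterior absorbs some residual collinearity
  between the weather covariates and the seasonal block, widening the
  predictive distribution slightly.
- **Power**: a 1.5× effect over 24 post months is flagged (cumulative
  interval excludes 0) in ≥90% of 50 replicates at 1,000 iterations, and
  the average pointwise effect recovers log 1.5.
- **Selection**: 30 covariates + 6 lags each (210 columns, 114 usable
  months), 3 active at a signal-to-noise ratio near 3: median posterior
  inclusion > 0.9 (active) and < 0.2 (null) across 20 seeds.
- Kernel exactness is checked against brute-force joint-Gaussian
  densities, closed-form smoother moments, and full spike-and-slab model
  enumeration on small instances.

These problem sizes keep a full run of the suite and the acceptance
script in the minutes range while leaving the Monte-Carlo error of each
check well inside its tolerance.

## Numerical notes and limitations

- The filter works with a proper 10⁶-scaled initialisation rather than an
  exact diffuse filter; at T ≥ 24 the difference is far below the
  Monte-Carlo noise of the sampler.  Log-likelihood values include all
  observation terms under that proper prior.
- Degenerate inputs: zero-variance models are handled exactly (the
  simulation smoother returns the deterministic smoothed path); a design
  column with zero variance raises a singular-slab error rather than
  silently regularising.
- The breakpoint BIC floors the RSS at n·10⁻¹²·var(x) so noiseless step
  fixtures select the minimal true segmentation instead of chasing −∞.
- Horizons beyond roughly two years become uninformative as trend
  uncertainty compounds — visible as the monotone widening of the
  predictive bands, and the reason the power experiment uses a 24-month
  post window.
- Under-recorded deaths bias Y_t downward by at most a fraction of the
  ~4% death share, which is negligible against month-to-month variation;
  the generator's thinning toggle lets a user verify this directly.
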