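# flowimpact

Counterfactual impact analysis of monthly migration-flow series with a
Bayesian structural time-series (BSTS) model.

## The problem

Did a policy change — a state-led search-and-rescue operation, the arrival
of private rescue NGOs, a pushback agreement — change the monthly flow of
irregular sea crossings on a migration route?  There is no control group:
the route is a single treated unit.  The standard answer is an interrupted
time series with a *synthetic counterfactual*: fit a predictive model to
the months before the intervention month τ, using exogenous "push and
pull" covariates (economic indices, weather, conflict and disaster
indicators, air-traffic flows), predict what the flow would have been
after τ without the intervention, and read the effect off the gap between
the observed and the predicted series.

The flow measure is the monthly count of crossing attempts,
`Y_t = A_t + P_t + D_t` — arrivals plus pushbacks plus recorded deaths —
and the model works on `log(Y_t + 1)`.  The BSTS model combines

- a local linear trend (level + slope random walks),
- a sum-to-zero monthly seasonal (period 12),
- a static regression on the covariate panel and its 1–6 month lags, with
  a **spike-and-slab prior** that selects a sparse predictive subset even
  when there are more candidate columns than months,

estimated by a blocked Gibbs sampler (simulation smoother for the states,
conjugate inverse-gamma draws for the variances, closed-form
normal–inverse-gamma scans for the regression).  Effects are computed per
posterior draw — pointwise (observed − predicted), cumulative, and the
posterior probability of an increase — so every reported band carries the
full posterior uncertainty.

Real flow series of this kind are compiled from proprietary sources, so
the package ships a synthetic-data module that generates flow and
covariate panels with the same structure and a known ground truth; every
stage of the pipeline is tested against it, plus brute-force oracles for
the numerical kernels.

## Worked example

```python
import numpy as np
import flowimpact as fi

# a synthetic ten-year route: 10 candidate covariates (5 truly active),
# and a pushback-style intervention multiplying the flow by 1.5 from
# month 60 onward
cfg = fi.ScenarioConfig(
    n_months=84, n_covariates=10, n_active=5,
    beta_active=(0.3, -0.25, 0.2, 0.2, -0.15),
    interventions=((60, 1.5),), seed=11)
flow, panel, truth = fi.generate_scenario(cfg)

spec = fi.InterventionSpec("pushback policy", flow.index[60])
result = fi.run_intervention_analysis(
    flow, panel, spec, mcmc=(2000, None), rng=11, max_lag=0)

s = result.summary()
avg = s["average_effect_log"]
print(s["classification"])
print("average effect (log): %.3f [%.3f, %.3f]"
      % (avg["median"], avg["lower"], avg["upper"]))
print("implied multiplier: %.2f" % np.exp(avg["median"]))
print("pre-fit MAPE %.1f%%" % result.pre_fit["one_step_mape_pct"])
```

prints

```
increase
average effect (log): 0.274 [0.126, 0.427]
implied multiplier: 1.32
pre-fit MAPE 7.0%
```

The injected 1.5× effect is flagged as a significant increase: the 95%
credible interval of the average post-period log effect excludes zero,
and the posterior median implies a 1.32× multiplier (one replicate's
estimate of the true 1.50).  The pre-period one-step MAPE of 7% says the
model tracked the training window closely — the prerequisite for trusting
the counterfactual.

The same analysis is available as a scikit-learn-style estimator
(`fi.CausalImpactAnalyzer(intervention=spec, ...).fit(flow, panel)`), and
the model core as `fi.BSTSModel` with `fit(X, y)` /
`sample_predictive(X)`.

## Command line

```bash
flowimpact simulate --config scenario.yaml --out data/
flowimpact impact   --config run.yaml --seed 3 --out results/
flowimpact diagnose --config run.yaml --out diagnostics/
```

`impact` runs the full pipeline (assembly → fit → counterfactual →
validation) for each configured intervention and writes per-month CSVs
plus a YAML summary; `diagnose` writes the classical trend/seasonal
decomposition, exact multiple-breakpoint segmentation, mortality rate per
1000 attempts, and the Granger exogeneity screen of covariates against
the interventions.  Re-running any command with the same config and seed
reproduces every CSV byte for byte.

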