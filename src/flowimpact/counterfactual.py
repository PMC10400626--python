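"""Counterfactual intervention analysis of a monthly flow series.

For an intervention starting in month tau, the analysis fits the
structural time-series model to the pre-intervention window only, then
propagates it over the post-intervention months using the observed
covariates (assumed unaffected by the intervention) to obtain the
posterior-predictive distribution of the flow had the intervention not
happened.  The pointwise effect in each post month is observed minus
predicted, computed per posterior draw and then summarized, so the
reported credible bands carry the full posterior uncertainty; the
cumulative effect is the running sum of pointwise effects.

All modelling is done on the log scale; count-scale summaries are obtained
by exponentiating each draw before summarizing (never by exponentiating a
summary, which would ignore the Jensen gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .assembly import (
    CovariatePanel,
    FlowSeries,
    InterventionSpec,
    build_design_matrix,
    log_transform,
    resolve_intervention_month,
)
from .bsts_core import BSTSModel, SpikeSlabPrior
from .errors import AlignmentError, AnalysisError

__all__ = [
    "CounterfactualResult",
    "CausalImpactAnalyzer",
    "run_intervention_analysis",
    "effect_significance",
    "run_three_period_study",
]


def _summary(draws: np.ndarray, level: float) -> pd.DataFrame:
    """Per-column median/mean and central credible bounds of a draw matrix."""
    lo = 50.0 * (1.0 - level)
    hi = 100.0 - lo
    return pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "median": np.percentile(draws, 50.0, axis=0),
            "lower": np.percentile(draws, lo, axis=0),
            "upper": np.percentile(draws, hi, axis=0),
        }
    )


@dataclass
class CounterfactualResult:
    """Post-period counterfactual prediction and effect summaries."""

    name: str
    tau: pd.Timestamp
    level: float
    observed_log: pd.Series           # full window, log scale
    predicted: pd.DataFrame           # post months x (mean, median, lower, upper), log
    pointwise: pd.DataFrame           # observed - predicted, summarized per month
    cumulative: pd.DataFrame          # running sum of pointwise effects
    predicted_counts: pd.DataFrame    # per-draw back-transformed summaries
    tail_prob: float                  # P(average post-period effect > 0)
    pre_fit: dict = field(default_factory=dict)
    inclusion_probs: pd.Series | None = None
    effect_draws_mean: np.ndarray | None = None  # per-draw average effect

    @property
    def average_effect(self) -> dict:
        """Posterior summary of the average pointwise effect (log scale)."""
        d = self.effect_draws_mean
        lo = 50.0 * (1.0 - self.level)
        return {
            "median": float(np.percentile(d, 50.0)),
            "lower": float(np.percentile(d, lo)),
            "upper": float(np.percentile(d, 100.0 - lo)),
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-month table (one row per post-period month)."""
        idx = self.predicted.index
        out = pd.DataFrame(index=idx)
        out["observed"] = self.observed_log.reindex(idx)
        for col in ("mean", "median", "lower", "upper"):
            out[f"predicted_{col}"] = self.predicted[col]
        for col in ("median", "lower", "upper"):
            out[f"pointwise_{col}"] = self.pointwise[col]
            out[f"cumulative_{col}"] = self.cumulative[col]
        for col in ("median", "lower", "upper"):
            out[f"predicted_count_{col}"] = self.predicted_counts[col]
        return out.rename_axis("month")

    def summary(self) -> dict:
        avg = self.average_effect
        return {
            "intervention": self.name,
            "tau": str(self.tau.date()),
            "level": self.level,
            "classification": effect_significance(self, self.level),
            "tail_prob_increase": float(self.tail_prob),
            "tail_prob_decrease": float(1.0 - self.tail_prob),
            "average_effect_log": avg,
            "cumulative_effect_log": {
                "median": float(self.cumulative["median"].iloc[-1]),
                "lower": float(self.cumulative["lower"].iloc[-1]),
                "upper": float(self.cumulative["upper"].iloc[-1]),
            },
            "pre_fit": {k: (float(v) if np.isscalar(v) else v)
                        for k, v in self.pre_fit.items()
                        if np.isscalar(v)},
        }

    def write(self, csv_path, yaml_path) -> None:
        self.to_frame().to_csv(csv_path, date_format="%Y-%m-%d")
        with open(yaml_path, "w") as fh:
            yaml.safe_dump(self.summary(), fh, sort_keys=False)


class CausalImpactAnalyzer(BaseEstimator):
    """Intervention analysis estimator: fit pre-period, predict post-period.

    ``fit(flow, panel)`` runs the full pipeline — log transform, lagged
    design construction (standardized on pre-period statistics only),
    pre/post split at tau, MCMC fit on the pre window, posterior-predictive
    counterfactual over the post window — and stores the
    :class:`CounterfactualResult` in ``result_``.

    Parameters
    ----------
    intervention : InterventionSpec
        Name and calendar start date; the month containing the start date
        is the first post-intervention month.
    horizon : int or None
        Number of post months to analyse (None = to the end of the data).
    max_lag : int
        Covariate lags added to the design (0..max_lag months).
    log_offset : float
        Offset used in the variance-stabilising log transform.
    level : float
        Credible level of all reported intervals (default 0.95).
    """

    def __init__(
        self,
        intervention: InterventionSpec | None = None,
        horizon: int | None = None,
        max_lag: int = 6,
        standardize: bool = True,
        log_offset: float = 1.0,
        level: float = 0.95,
        components: tuple = ("trend", "seasonal"),
        season_period: int = 12,
        expected_model_size: float = 5.0,
        kappa: float = 1.0,
        n_iter: int = 2000,
        n_burn: int | None = None,
        min_pre_months: int = 24,
        random_state=None,
    ):
        self.intervention = intervention
        self.horizon = horizon
        self.max_lag = max_lag
        self.standardize = standardize
        self.log_offset = log_offset
        self.level = level
        self.components = components
        self.season_period = season_period
        self.expected_model_size = expected_model_size
        self.kappa = kappa
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.min_pre_months = min_pre_months
        self.random_state = random_state

    def fit(self, flow: FlowSeries, panel: CovariatePanel | None = None):
        if self.intervention is None:
            raise AnalysisError("an InterventionSpec is required")
        if not 0 < self.level < 1:
            raise AnalysisError("level must lie in (0, 1)")
        rng = (self.random_state
               if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        tau = resolve_intervention_month(self.intervention, flow.index)

        y_log = log_transform(flow, offset=self.log_offset)
        if panel is not None and len(panel.columns):
            if not panel.index.equals(flow.index):
                raise AlignmentError("panel and flow must share the month index")
            design = build_design_matrix(
                panel, max_lag=self.max_lag, standardize=self.standardize,
                stats_through=tau,
            )
            idx = design.index
            Xfull = design.data.to_numpy(float)
            self.design_columns_ = list(design.columns)
        else:
            idx = flow.index
            Xfull = None
            self.design_columns_ = []
        y = y_log.reindex(idx)

        pre_mask = np.asarray(idx < tau)
        post_mask = ~pre_mask
        n_pre = int(pre_mask.sum())
        n_post = int(post_mask.sum())
        if n_pre < self.min_pre_months:
            raise AnalysisError(
                f"only {n_pre} pre-intervention months before {tau.date()}; "
                f"{self.min_pre_months} required"
            )
        if n_post < 1:
            raise AnalysisError("no post-intervention months to analyse")
        if self.horizon is not None:
            n_post = min(n_post, int(self.horizon))
        post_idx = idx[post_mask][:n_post]

        y_pre = y[pre_mask].to_numpy()
        X_pre = Xfull[pre_mask] if Xfull is not None else None
        X_post = Xfull[post_mask][:n_post] if Xfull is not None else None

        model = BSTSModel(
            components=self.components, season_period=self.season_period,
            expected_model_size=self.expected_model_size, kappa=self.kappa,
            n_iter=self.n_iter, n_burn=self.n_burn,
            min_pre_months=self.min_pre_months, random_state=rng,
        ).fit(X_pre, y_pre)
        self.model_ = model

        pred = model.sample_predictive(X_post, horizon=n_post, random_state=rng)
        obs_post = y[post_mask][:n_post].to_numpy()

        effects = obs_post[None, :] - pred          # (m, n_post)
        cum = effects.cumsum(axis=1)
        counts = np.exp(pred) - self.log_offset      # per-draw back-transform

        predicted = _summary(pred, self.level).set_index(post_idx)
        pointwise = _summary(effects, self.level).set_index(post_idx)
        cumulative = _summary(cum, self.level).set_index(post_idx)
        predicted_counts = _summary(counts, self.level).set_index(post_idx)
        avg_draws = effects.mean(axis=1)
        tail_prob = float((avg_draws > 0).mean())

        incl = None
        if self.design_columns_:
            incl = pd.Series(model.inclusion_probs_, index=self.design_columns_)

        result = CounterfactualResult(
            name=self.intervention.name, tau=tau, level=self.level,
            observed_log=y, predicted=predicted, pointwise=pointwise,
            cumulative=cumulative, predicted_counts=predicted_counts,
            tail_prob=tail_prob, inclusion_probs=incl,
            effect_draws_mean=avg_draws,
        )
        result.pre_fit = self._pre_period_fit(model, y_pre)
        self.result_ = result
        return self

    def _pre_period_fit(self, model: BSTSModel, y_pre: np.ndarray) -> dict:
        """One-step-ahead fit metrics on the training window.

        The first season of months is excluded: under the weakly
        informative initialisation the filter needs roughly one seasonal
        cycle before its one-step predictions are informative.
        """
        from scipy import stats

        mean, sd = model.one_step_ahead()
        skip = min(self.season_period + 2, y_pre.size - 4)
        obs = y_pre[skip:]
        mu = mean[skip:]
        s = sd[skip:]
        zcrit = stats.norm.ppf(0.5 + self.level / 2.0)
        inside = np.abs(obs - mu) <= zcrit * s
        obs_c = np.exp(obs) - self.log_offset
        mu_c = np.exp(mu) - self.log_offset
        ok = obs_c > 0
        mape = float(np.mean(np.abs(obs_c[ok] - mu_c[ok]) / obs_c[ok])) * 100.0
        resid = (obs - mu) / s
        return {
            "one_step_mape_pct": mape,
            "coverage": float(inside.mean()),
            "residuals": resid,
            "n_evaluated": int(obs.size),
        }


def run_intervention_analysis(
    flow: FlowSeries,
    panel: CovariatePanel | None,
    spec: InterventionSpec,
    prior: SpikeSlabPrior | None = None,
    mcmc: tuple = (2000, None),
    rng=None,
    **options,
) -> CounterfactualResult:
    """Functional wrapper over :class:`CausalImpactAnalyzer`."""
    n_iter, n_burn = mcmc
    opts = dict(options)
    n_iter = opts.pop("n_iter", n_iter)
    n_burn = opts.pop("n_burn", n_burn)
    if prior is not None:
        opts.setdefault("expected_model_size", prior.expected_model_size)
        opts.setdefault("kappa", prior.kappa)
    analyzer = CausalImpactAnalyzer(
        intervention=spec, n_iter=n_iter, n_burn=n_burn, random_state=rng,
        **opts,
    )
    analyzer.fit(flow, panel)
    return analyzer.result_


def effect_significance(result: CounterfactualResult, level: float | None = None) -> str:
    """Classify the intervention effect from the average-effect interval.

    Returns ``"increase"`` if the credible interval of the average
    post-period effect lies above 0, ``"decrease"`` if below, and
    ``"indistinguishable"`` if the interval straddles 0.
    """
    if level is None or level == result.level:
        avg = result.average_effect
    else:
        d = result.effect_draws_mean
        lo = 50.0 * (1.0 - level)
        avg = {
            "median": float(np.percentile(d, 50.0)),
            "lower": float(np.percentile(d, lo)),
            "upper": float(np.percentile(d, 100.0 - lo)),
        }
    if avg["lower"] > 0:
        return "increase"
    if avg["upper"] < 0:
        return "decrease"
    return "indistinguishable"


def run_three_period_study(
    flow: FlowSeries,
    panel: CovariatePanel | None,
    specs: Sequence[InterventionSpec],
    rng=None,
    **options,
) -> list[CounterfactualResult]:
    """Analyse several interventions independently on one dataset.

    Each intervention is analysed with its own pre-period (all months
    before its own tau); the specs must be ordered in time.  Later
    post-periods overlap later interventions, so individual results cannot
    separate delayed effects of earlier interventions from direct effects
    of later ones — interpret each result as the joint effect of everything
    changing from its tau onward.
    """
    taus = [s.tau_month for s in specs]
    if any(b < a for a, b in zip(taus, taus[1:])):
        raise ValueError("intervention specs must be ordered in time")
    if isinstance(rng, np.random.Generator):
        base_seed = int(rng.integers(2**31))
    else:
        base_seed = int(rng) if rng is not None else 0
    results = []
    for spec in specs:
        # child seed keyed on the intervention month: the same spec always
        # gets the same stream, independent of its position in the list
        child = np.random.default_rng(
            [base_seed, spec.tau_month.year, spec.tau_month.month]
        )
        results.append(
            run_intervention_analysis(flow, panel, spec, rng=child, **options)
        )
    return results
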