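"""State-space engine: filter, smoothers, spike-and-slab, Gibbs sampler.

Each numerical routine is checked against an independent closed-form or
brute-force oracle on small instances (joint-Gaussian density for the
filter, conditional-Gaussian moments for the smoothers, full model
enumeration for the spike-and-slab posterior).
"""

import numpy as np
import pytest
from scipy.special import gammaln

import flowimpact as fi
from flowimpact.bsts_core import (
    SpikeSlabSampler,
    one_step_predictions,
    sample_spike_slab,
)
from flowimpact.errors import ConfigError, SamplerError
from conftest import brute_force_loglik, local_level_model, random_proper_model


class TestBuildModel:
    def test_trend_canonical_form(self):
        m = fi.build_model(components=("trend",))
        assert m.d == 2
        assert np.array_equal(m.T, [[1.0, 1.0], [0.0, 1.0]])
        assert np.array_equal(m.Z, [1.0, 0.0])

    def test_trend_plus_seasonal_dimension(self):
        m = fi.build_model(components=("trend", "seasonal"), s=12)
        assert m.d == 2 + 11

    def test_observation_selects_current_seasonal_state(self):
        m = fi.build_model(components=("trend", "seasonal"), s=12)
        alpha = np.zeros(m.d)
        alpha[0] = 5.0   # level
        alpha[2] = 1.5   # current seasonal state
        alpha[3:] = 9.9  # older seasonal states must not enter
        assert m.Z @ alpha == pytest.approx(6.5)

    def test_seasonal_state_recursion_sums_to_zero(self):
        m = fi.build_model(components=("seasonal",), s=4, seasonal_var=0.0)
        alpha = np.array([1.0, -2.0, 0.5])
        nxt = m.T @ alpha
        # noiseless: new seasonal state = -(sum of previous s-1 states)
        assert nxt[0] == pytest.approx(-(1.0 - 2.0 + 0.5))

    def test_unknown_component(self):
        with pytest.raises(ConfigError):
            fi.build_model(components=("cycle",))


class TestKalmanFilter:
    def test_constant_series_known_loglik(self):
        # level variance 0, obs variance 1, y == c, exact prior at c:
        # every one-step density is N(c; c, 1)
        m = local_level_model(level_var=0.0, sigma2=1.0, a1=3.0, P1=0.0)
        n = 8
        fr = fi.kalman_filter(m, np.full(n, 3.0))
        assert fr.loglik == pytest.approx(-(n / 2) * np.log(2 * np.pi))

    def test_matches_brute_force_joint_gaussian(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            m = random_proper_model(rng)
            n = int(rng.integers(3, 12))
            y = rng.normal(0, 2, n)
            assert fi.kalman_filter(m, y).loglik == pytest.approx(
                brute_force_loglik(m, y), abs=1e-8)

    def test_missing_value_marginalizes(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = random_proper_model(rng)
            y = rng.normal(0, 2, 6)
            y[int(rng.integers(0, 6))] = np.nan
            assert fi.kalman_filter(m, y).loglik == pytest.approx(
                brute_force_loglik(m, y), abs=1e-8)

    def test_nonfinite_input_rejected(self):
        m = local_level_model()
        with pytest.raises(fi.errors.NumericError):
            fi.kalman_filter(m, np.array([1.0, np.inf, 2.0]))


def _closed_form_conditional(model, y):
    """Exact smoothed mean/cov of a local-level state given all data."""
    n = len(y)
    P1 = model.P1[0, 0]
    q = model.Q[0, 0]
    diagv = P1 + q * np.arange(n)
    Valpha = np.minimum.outer(diagv, diagv)
    Valpha = np.minimum(Valpha, np.minimum.outer(diagv, diagv))
    # Cov(alpha_s, alpha_t) = Var(alpha_min(s,t))
    idx = np.minimum.outer(np.arange(n), np.arange(n))
    Valpha = diagv[idx]
    S = Valpha + np.eye(n) * model.sigma2
    mu = model.a1[0] + Valpha @ np.linalg.solve(S, y - model.a1[0])
    V = Valpha - Valpha @ np.linalg.solve(S, Valpha)
    return mu, V


class TestSmoothers:
    def setup_method(self):
        self.model = local_level_model(level_var=0.5, sigma2=1.0, a1=0.0, P1=2.0)
        self.y = np.array([1.0, 2.0, 1.5, 3.0, 2.5])

    def test_smoother_matches_closed_form(self):
        mu, V = _closed_form_conditional(self.model, self.y)
        ah, Vh = fi.kalman_smoother(self.model, self.y, want_cov=True)
        assert np.allclose(ah[:, 0], mu, atol=1e-10)
        assert np.allclose(Vh[:, 0, 0], np.diag(V), atol=1e-10)

    def test_zero_variance_draw_is_deterministic_smooth(self):
        m = local_level_model(level_var=0.0, sigma2=1.0, a1=2.0, P1=0.0)
        rng = np.random.default_rng(0)
        draw = fi.simulation_smoother(m, self.y, rng)
        ah = fi.kalman_smoother(m, self.y)
        assert np.allclose(draw, ah, atol=1e-12)

    def test_simulation_smoother_moments(self):
        # empirical mean/cov of 20k draws vs the conditional Gaussian
        mu, V = _closed_form_conditional(self.model, self.y)
        rng = np.random.default_rng(3)
        draws = np.array([
            fi.simulation_smoother(self.model, self.y, rng)[:, 0]
            for _ in range(20_000)
        ])
        se = np.sqrt(np.diag(V) / draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 3 * se)
        cov_err = np.abs(np.cov(draws.T) - V)
        assert cov_err.max() < 4 * np.abs(V).max() / np.sqrt(draws.shape[0] / 10)


def _enumeration_posterior(X, z, sampler, pi):
    """Exact posterior inclusion probabilities by enumerating all models."""
    n, p = X.shape
    nu, ss0 = sampler.nu, sampler.ss0

    def logml(idx):
        idx = np.asarray(idx, int)
        Xtz = X.T @ z
        ztz = z @ z
        if idx.size == 0:
            ssn, ld = ss0 + ztz, 0.0
        else:
            V0 = sampler.V0inv[np.ix_(idx, idx)]
            Vn = sampler.XtX[np.ix_(idx, idx)] + V0
            b = Xtz[idx]
            ssn = ss0 + ztz - b @ np.linalg.solve(Vn, b)
            ld = 0.5 * (np.linalg.slogdet(V0)[1] - np.linalg.slogdet(Vn)[1])
        return (ld + gammaln((nu + n) / 2) - ((nu + n) / 2) * np.log(ssn / 2))

    from itertools import combinations
    models, lps = [], []
    for k in range(p + 1):
        for combo in combinations(range(p), k):
            models.append(set(combo))
            prior = sum(np.log(pi) if j in combo else np.log(1 - pi)
                        for j in range(p))
            lps.append(logml(list(combo)) + prior)
    lps = np.array(lps)
    w = np.exp(lps - lps.max())
    w /= w.sum()
    return np.array([
        sum(wi for wi, mset in zip(w, models) if j in mset) for j in range(p)
    ])


class TestSpikeSlab:
    def _fixture(self, p=2, n=12, seed=42, noise=0.5):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, p))
        beta = np.zeros(p)
        beta[0] = 1.2
        z = X @ beta + rng.normal(0, noise, n)
        return X, z

    def test_zero_prior_probability_never_included(self):
        X, z = self._fixture()
        prior = fi.SpikeSlabPrior(pi=np.array([0.0, 0.5]))
        rng = np.random.default_rng(0)
        gamma = np.ones(2, dtype=bool)
        for _ in range(50):
            gamma, beta, _ = sample_spike_slab(z, X, prior, rng, gamma)
            assert not gamma[0]
            assert beta[0] == 0.0

    def test_excluded_coefficients_exactly_zero(self):
        X, z = self._fixture(p=4)
        prior = fi.SpikeSlabPrior(pi=0.3)
        rng = np.random.default_rng(1)
        gamma = np.zeros(4, dtype=bool)
        for _ in range(50):
            gamma, beta, _ = sample_spike_slab(z, X, prior, rng, gamma)
            assert np.all(beta[~gamma] == 0.0)

    def test_near_deterministic_column_always_selected(self):
        # one column equals the target up to vanishing noise: its marginal
        # likelihood ratio diverges and inclusion frequency goes to 1
        rng = np.random.default_rng(5)
        n = 30
        X = np.column_stack([rng.normal(0, 1, n), rng.normal(0, 1, n)])
        z = X[:, 0] + rng.normal(0, 1e-4, n)
        prior = fi.SpikeSlabPrior(pi=0.5)
        gamma = np.zeros(2, dtype=bool)
        hits = 0
        for _ in range(200):
            gamma, _, _ = sample_spike_slab(z, X, prior, rng, gamma)
            hits += gamma[0]
        assert hits == 200

    def test_gibbs_matches_enumeration(self):
        # exact posterior over all 2^p models vs Gibbs inclusion rates
        X, z = self._fixture(p=2, n=12)
        prior = fi.SpikeSlabPrior(pi=0.5, kappa=1.0, nu=1.0, s2=0.5)
        sampler = SpikeSlabSampler(X, prior, s2_default=0.5)
        exact = _enumeration_posterior(X, z, sampler, pi=0.5)
        rng = np.random.default_rng(9)
        gamma = np.zeros(2, dtype=bool)
        nscan = 5000
        counts = np.zeros(2)
        for _ in range(nscan):
            gamma, _, _ = sampler.draw(z, gamma, rng)
            counts += gamma
        freq = counts / nscan
        se = np.sqrt(exact * (1 - exact) / nscan) * 3  # ~independent scans
        tol = np.maximum(3 * se, 0.02)
        assert np.all(np.abs(freq - exact) < tol)

    def test_more_columns_than_rows_supported(self):
        rng = np.random.default_rng(3)
        n, p = 20, 40
        X = rng.normal(0, 1, (n, p))
        z = X[:, 0] * 0.8 + rng.normal(0, 0.3, n)
        prior = fi.SpikeSlabPrior(expected_model_size=3.0)
        gamma, beta, sigma2 = sample_spike_slab(z, X, prior,
                                                np.random.default_rng(0))
        assert beta.shape == (p,)
        assert sigma2 > 0


class TestFitBSTS:
    def test_same_seed_identical_draws(self):
        rng = np.random.default_rng(0)
        y = 5 + 0.1 * np.arange(40) + rng.normal(0, 0.2, 40)
        d1, _ = fi.fit_bsts(y, None, n_iter=100, rng=7, components=("trend",))
        d2, _ = fi.fit_bsts(y, None, n_iter=100, rng=7, components=("trend",))
        assert np.array_equal(d1.states, d2.states)
        assert np.array_equal(d1.sigma2, d2.sigma2)

    def test_short_series_rejected(self):
        with pytest.raises(SamplerError):
            fi.fit_bsts(np.ones(10), None, n_iter=10)

    def test_trend_recovery_band(self):
        # posterior 95% band of the level path should cover the truth at
        # nearly all time points in a well-specified trend-only problem
        rng = np.random.default_rng(12)
        T = 80
        level = 7 + np.cumsum(rng.normal(0, 0.02, T))
        y = level + rng.normal(0, 0.05, T)
        # weak variance priors: this experiment checks the likelihood's
        # ability to track the state path, not the default shrinkage
        draws, _ = fi.fit_bsts(y, None, n_iter=800, rng=3,
                               components=("trend",), variance_prior_df=0.01)
        lv = draws.states[:, :, 0]
        lo, hi = np.percentile(lv, [2.5, 97.5], axis=0)
        frac = np.mean((level >= lo) & (level <= hi))
        assert frac >= 0.9

    def test_covariate_recovery_small(self):
        cfg = fi.ScenarioConfig(n_months=120, n_covariates=12, n_active=3,
                                beta_active=(0.3, -0.25, 0.2), seed=21)
        flow, panel, truth = fi.generate_scenario(cfg)
        design = fi.build_design_matrix(panel, max_lag=0, standardize=True)
        y = fi.log_transform(flow).to_numpy()
        m = fi.BSTSModel(n_iter=600, random_state=2).fit(
            design.data.to_numpy(), y)
        incl = dict(zip(design.columns, m.inclusion_probs_))
        active = [incl[c] for c in truth.active]
        null = [v for c, v in incl.items() if c not in truth.active]
        assert min(active) > 0.9
        assert np.median(null) < 0.2


class TestPosteriorPredict:
    def _degenerate_draws(self, c=4.0, m=200):
        model = fi.build_model(components=("trend",), level_var=0.0,
                               slope_var=0.0)
        states = np.zeros((m, 10, 2))
        states[:, :, 0] = c
        draws = fi.PosteriorDraws(
            states=states, sigma2=np.full(m, 1e-300),
            variances={"level": np.zeros(m), "slope": np.zeros(m)},
            gamma=np.zeros((m, 0), bool), beta=np.zeros((m, 0)),
            n_iter=m, n_burn=0, components=("trend",),
        )
        return draws, model

    def test_all_variances_zero_constant_paths(self):
        draws, model = self._degenerate_draws(c=4.0)
        paths = fi.posterior_predict(draws, model, None, horizon=6, rng=0)
        assert np.allclose(paths, 4.0, atol=1e-9)

    def test_one_step_forecast_moments(self):
        # h=1 predictive draws must match the Kalman one-step forecast:
        # mean Z T a_hat_T, variance Z (T V_T T' + RQR) Z' + sigma2
        model = local_level_model(level_var=0.3, sigma2=1.0, a1=0.0, P1=2.0)
        y = np.array([1.0, 2.0, 1.5, 3.0, 2.5])
        ah, V = fi.kalman_smoother(model, y, want_cov=True)
        mean_T, var_T = ah[-1, 0], V[-1, 0, 0]
        m = 40_000
        rng = np.random.default_rng(8)
        states = np.zeros((m, len(y), 1))
        states[:, -1, 0] = mean_T + np.sqrt(var_T) * rng.standard_normal(m)
        draws = fi.PosteriorDraws(
            states=states, sigma2=np.full(m, model.sigma2),
            variances={"level": np.full(m, 0.3)},
            gamma=np.zeros((m, 0), bool), beta=np.zeros((m, 0)),
            n_iter=m, n_burn=0,
        )
        pred_model = fi.StateSpaceModel(
            Z=[1.0], T=[[1.0]], R=[[1.0]], Q=[[0.3]], sigma2=1.0,
            a1=[0.0], P1=[[2.0]])
        pred_model._dist_index = {"level": 0}
        paths = fi.posterior_predict(draws, pred_model, None, horizon=1, rng=1)
        exp_mean = mean_T
        exp_var = var_T + 0.3 + 1.0
        assert paths.mean() == pytest.approx(exp_mean,
                                             abs=4 * np.sqrt(exp_var / m))
        assert paths.var() == pytest.approx(exp_var, rel=0.05)

    def test_quantiles_monotone(self):
        draws, model = self._degenerate_draws()
        draws.sigma2 = np.full(draws.n_kept, 0.5)
        paths = fi.posterior_predict(draws, model, None, horizon=4, rng=2)
        qs = np.percentile(paths, [5, 25, 50, 75, 95], axis=0)
        assert np.all(np.diff(qs, axis=0) >= 0)

    def test_horizon_mismatch(self):
        draws, model = self._degenerate_draws()
        draws.beta = np.zeros((draws.n_kept, 2))
        with pytest.raises(ConfigError):
            fi.posterior_predict(draws, model, np.ones((3, 2)), horizon=5)


class TestSeasonalIdentifiability:
    def test_posterior_seasonal_sums_near_zero(self):
        cfg = fi.ScenarioConfig(n_months=72, n_covariates=0, n_active=0,
                                seasonal_sd=0.2, seed=13)
        flow, _, _ = fi.generate_scenario(cfg)
        y = fi.log_transform(flow).to_numpy()
        draws, model = fi.fit_bsts(y, None, n_iter=400, rng=5)
        se = model.blocks["seasonal"]
        seas = draws.states[:, :, se.start]  # current seasonal state path
        # any 12 consecutive seasonal values nearly cancel
        sums = np.abs(np.array([
            seas[:, t:t + 12].sum(axis=1) for t in range(0, 60, 12)
        ]))
        assert sums.mean() < 3 * np.sqrt(np.median(draws.variances["seasonal"])) * 12


class TestOneStepPredictions:
    def test_white_noise_level_model(self):
        model = fi.build_model(components=("trend",), level_var=0.0,
                               slope_var=0.0, sigma2=1.0)
        model.a1[:] = [5.0, 0.0]
        model.P1[:] = 0.0
        y = np.full(30, 5.0)
        mean, sd = one_step_predictions(
            model, y, None, np.zeros(0), {"level": 0.0, "slope": 0.0}, 1.0)
        assert np.allclose(mean, 5.0)
        assert np.allclose(sd, 1.0)
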