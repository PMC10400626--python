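"""Bayesian structural time-series engine.

A structural time-series model for a monthly log-count series combines a
local linear trend, a sum-to-zero dummy seasonal of period 12, and a static
sparse regression on a wide covariate panel.  In state-space form the
observation equation is

    y_t = Z' alpha_t + x_t' beta + eps_t,        eps_t ~ N(0, sigma2)

and the state equation

    alpha_{t+1} = T alpha_t + R eta_t,           eta_t ~ N(0, Q)

with alpha_t stacking (level, slope, seasonal states).  Posterior inference
uses a blocked Gibbs sampler: (i) a simulation-smoother draw of the full
state path, (ii) inverse-gamma draws of the component disturbance
variances, (iii) a spike-and-slab draw of (gamma, beta, sigma2) on the
observation residual, which performs Bayesian variable selection even when
the design has more columns than time points.

Everything here is written directly against the recursions (Kalman filter,
disturbance smoother, mean-correction simulation smoother, conjugate
normal-inverse-gamma updates); no state-space library is used, so small
closed-form oracles in the test-suite can verify each piece independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from scipy.linalg.lapack import dpotrf, dtrtrs
from sklearn.base import BaseEstimator

from ._kernels import filter_core, simulate_states_core, smoother_core
from .errors import ConfigError, NumericError, SamplerError

__all__ = [
    "StateSpaceModel",
    "FilterResult",
    "SpikeSlabPrior",
    "SpikeSlabSampler",
    "PosteriorDraws",
    "build_model",
    "kalman_filter",
    "kalman_smoother",
    "simulation_smoother",
    "sample_spike_slab",
    "fit_bsts",
    "posterior_predict",
    "one_step_predictions",
    "BSTSModel",
]


# ---------------------------------------------------------------------------
# model container and construction

@dataclass
class StateSpaceModel:
    """A linear-Gaussian state-space model with time-invariant matrices.

    ``Z`` is the d-vector mapping the state to the observation, ``T`` the
    d x d transition matrix, ``R`` the d x q disturbance-loading matrix and
    ``Q`` the q x q disturbance covariance; ``sigma2`` is the observation
    noise variance.  ``a1``/``P1`` give the proper Gaussian initial state
    distribution.  ``blocks`` maps component names to state slices and
    ``beta`` holds static regression coefficients entering the observation
    as a mean shift.
    """

    Z: np.ndarray
    T: np.ndarray
    R: np.ndarray
    Q: np.ndarray
    sigma2: float
    a1: np.ndarray
    P1: np.ndarray
    blocks: dict[str, slice] = field(default_factory=dict)
    season_period: int = 0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, float).ravel()
        self.T = np.atleast_2d(np.asarray(self.T, float))
        self.R = np.atleast_2d(np.asarray(self.R, float))
        self.Q = np.atleast_2d(np.asarray(self.Q, float))
        self.a1 = np.asarray(self.a1, float).ravel()
        self.P1 = np.atleast_2d(np.asarray(self.P1, float))
        d = self.Z.size
        if self.T.shape != (d, d) or self.R.shape[0] != d:
            raise ConfigError("inconsistent state-space dimensions")
        q = self.R.shape[1]
        if self.Q.shape != (q, q):
            raise ConfigError("Q must be q x q with q = R column count")
        if self.sigma2 <= 0:
            raise ConfigError("observation variance must be positive")
        eig = np.linalg.eigvalsh((self.Q + self.Q.T) / 2)
        if eig.min() < -1e-10 * max(1.0, eig.max()):
            raise ConfigError("Q must be positive semi-definite")

    @property
    def d(self) -> int:
        return self.Z.size

    @property
    def q(self) -> int:
        return self.R.shape[1]

    def set_variances(self, **component_vars: float) -> None:
        """Update the diagonal of Q by disturbance name (level/slope/seasonal)."""
        for name, v in component_vars.items():
            idx = self._dist_index[name]
            self.Q[idx, idx] = v

    # filled by build_model: disturbance name -> Q diagonal position
    _dist_index: dict[str, int] = field(default_factory=dict, repr=False)


def build_model(
    components: Sequence[str] = ("trend", "seasonal"),
    s: int = 12,
    n_covariates: int = 0,
    sigma2: float = 1.0,
    level_var: float = 1.0,
    slope_var: float = 1.0,
    seasonal_var: float = 1.0,
    a1: np.ndarray | None = None,
    init_var: float = 1e6,
) -> StateSpaceModel:
    """Assemble the block state-space matrices for the requested components.

    ``trend`` contributes a local linear trend (level + slope, 2 states);
    ``seasonal`` a sum-to-zero dummy seasonal with ``s - 1`` states whose
    newest state equals minus the sum of the previous ``s - 1`` plus noise.
    The regression enters the observation equation as a mean shift
    ``x_t' beta`` (coefficients stored on the model), not as extra states.
    """
    known = {"trend", "seasonal"}
    unknown = set(components) - known
    if unknown:
        raise ConfigError(f"unknown components {sorted(unknown)}")
    if "seasonal" in components and s < 2:
        raise ConfigError("seasonal period must be >= 2")

    blocks: dict[str, slice] = {}
    dist_index: dict[str, int] = {}
    Zs, Tblocks, Rcols, Qdiag = [], [], [], []
    d = 0
    q = 0
    if "trend" in components:
        blocks["trend"] = slice(d, d + 2)
        Zs.append(np.array([1.0, 0.0]))
        Tblocks.append(np.array([[1.0, 1.0], [0.0, 1.0]]))
        Rcols.append((d, 2))
        dist_index["level"] = q
        dist_index["slope"] = q + 1
        Qdiag += [level_var, slope_var]
        d += 2
        q += 2
    if "seasonal" in components:
        m = s - 1
        blocks["seasonal"] = slice(d, d + m)
        z = np.zeros(m)
        z[0] = 1.0
        Zs.append(z)
        Tb = np.zeros((m, m))
        Tb[0, :] = -1.0
        for i in range(1, m):
            Tb[i, i - 1] = 1.0
        Tblocks.append(Tb)
        Rcols.append((d, 1))
        dist_index["seasonal"] = q
        Qdiag.append(seasonal_var)
        d += m
        q += 1
    if d == 0:
        raise ConfigError("at least one of trend/seasonal must be requested")

    Z = np.concatenate(Zs)
    T = sla.block_diag(*Tblocks)
    R = np.zeros((d, q))
    col = 0
    for start, width in Rcols:
        for k in range(width):
            R[start + k, col] = 1.0
            col += 1
    Q = np.diag(Qdiag).astype(float)
    if a1 is None:
        a1 = np.zeros(d)
    P1 = np.eye(d) * init_var
    model = StateSpaceModel(
        Z=Z, T=T, R=R, Q=Q, sigma2=sigma2, a1=a1, P1=P1,
        blocks=blocks, season_period=s if "seasonal" in components else 0,
        beta=np.zeros(n_covariates),
    )
    model._dist_index = dist_index
    return model


# ---------------------------------------------------------------------------
# Kalman filter / smoother / simulation smoother

@dataclass
class FilterResult:
    a: np.ndarray        # (T, d) one-step-predicted state means a_t = E[alpha_t | y_{1:t-1}]
    P: np.ndarray        # (T, d, d) predicted covariances
    att: np.ndarray      # (T, d) filtered means
    Ptt: np.ndarray      # (T, d, d) filtered covariances
    v: np.ndarray        # (T,) one-step prediction errors (nan where missing)
    F: np.ndarray        # (T,) prediction-error variances (nan where missing)
    loglik: float
    observed: np.ndarray  # (T,) bool


def kalman_filter(model: StateSpaceModel, y: np.ndarray) -> FilterResult:
    """Run the Kalman filter; missing observations (NaN) skip the update.

    The log-likelihood is the exact joint Gaussian log-density of the
    observed entries under the proper initial distribution.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    if n < 1:
        raise NumericError("empty observation series")
    observed = ~np.isnan(y)
    if not np.all(np.isfinite(y[observed])):
        raise NumericError("observations contain non-finite values")
    RQR = model.R @ model.Q @ model.R.T
    a, P, att, Ptt, v, F, loglik, ok = filter_core(
        y, model.Z, model.T, RQR, float(model.sigma2),
        model.a1.astype(float), model.P1.astype(float),
    )
    if not ok:
        raise NumericError("non-positive prediction variance in the filter")
    return FilterResult(a=a, P=P, att=att, Ptt=Ptt, v=v, F=F,
                        loglik=float(loglik), observed=observed)


def kalman_smoother(
    model: StateSpaceModel, y: np.ndarray, want_cov: bool = False
):
    """Fixed-interval smoother (disturbance-smoother form, no inversions).

    Returns the smoothed state means ``(T, d)``; with ``want_cov`` also the
    smoothed covariances ``(T, d, d)``.
    """
    fr = kalman_filter(model, y)
    if not want_cov:
        return smoother_core(fr.a, fr.P, fr.v, fr.F, fr.observed,
                             model.Z, model.T)
    n, d = fr.a.shape
    Z, T = model.Z, model.T
    alphahat = np.empty((n, d))
    r = np.zeros(d)
    N = np.zeros((d, d))
    V = np.empty((n, d, d))
    ZZ = np.outer(Z, Z)
    for t in range(n - 1, -1, -1):
        if fr.observed[t]:
            Finv = 1.0 / fr.F[t]
            K = T @ (fr.P[t] @ Z) * Finv  # predictive-form gain
            L = T - np.outer(K, Z)
            r_prev = Z * (fr.v[t] * Finv) + L.T @ r
            N_prev = ZZ * Finv + L.T @ N @ L
        else:
            r_prev = T.T @ r
            N_prev = T.T @ N @ T
        alphahat[t] = fr.a[t] + fr.P[t] @ r_prev
        V[t] = fr.P[t] - fr.P[t] @ N_prev @ fr.P[t]
        N = N_prev
        r = r_prev
    return alphahat, V


def _simulate_unconditional(model: StateSpaceModel, n: int, rng):
    """Draw (alpha+, y+) from the model's unconditional joint distribution."""
    d, q = model.d, model.q
    # P1 is diagonal in all models built here; keep a general fallback
    P1 = model.P1
    if np.allclose(P1, np.diag(np.diagonal(P1))):
        alpha0 = model.a1 + rng.standard_normal(d) * np.sqrt(np.diagonal(P1))
    else:
        alpha0 = rng.multivariate_normal(model.a1, P1)
    qsd = np.sqrt(np.diagonal(model.Q))
    eta = rng.standard_normal((n, q)) * qsd
    alpha = simulate_states_core(np.asarray(alpha0, float), model.T, model.R, eta)
    yplus = alpha @ model.Z + rng.standard_normal(n) * np.sqrt(model.sigma2)
    return alpha, yplus


def simulation_smoother(
    model: StateSpaceModel, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One joint draw of the state path from p(alpha | y).

    Mean-correction construction: simulate an unconditional replicate
    (alpha+, y+), smooth the difference series y - y+ (with zero initial
    mean, so the affine constant cancels), and add alpha+ back.  Exact in
    the linear-Gaussian model with a proper initial distribution.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    alpha_plus, y_plus = _simulate_unconditional(model, n, rng)
    diff = y - y_plus  # NaN where y missing: smoother skips those updates
    RQR = model.R @ model.Q @ model.R.T
    a, P, att, Ptt, v, F, _, ok = filter_core(
        diff, model.Z, model.T, RQR, float(model.sigma2),
        np.zeros(model.d), model.P1.astype(float),
    )
    if not ok:
        raise NumericError("non-positive prediction variance in the filter")
    correction = smoother_core(a, P, v, F, ~np.isnan(diff), model.Z, model.T)
    return alpha_plus + correction


# ---------------------------------------------------------------------------
# spike-and-slab regression

@dataclass
class SpikeSlabPrior:
    """Spike-and-slab prior for the static regression block.

    A point mass at zero (the spike) with prior inclusion probability
    ``pi_j`` is mixed with a Zellner-style conditional Gaussian slab
    ``beta_gamma | sigma2 ~ N(0, sigma2 * Omega_gamma)`` whose precision is
    the information in ``kappa`` prior observations,

        Omega^{-1} = (kappa / n) * [w * X'X + (1 - w) * diag(X'X)],

    averaged with its diagonal (weight ``1 - w``) so the prior stays proper
    when the design has more columns than rows.  The observation variance
    gets a conjugate inverse-gamma prior worth ``nu`` observations with
    prior guess ``s2`` (by default half the sample variance of the target,
    i.e. an expected R-squared of one half).
    """

    pi: float | np.ndarray | None = None
    expected_model_size: float = 5.0
    kappa: float = 1.0
    diagonal_weight: float = 0.5
    nu: float = 0.01
    s2: float | None = None

    def inclusion_probs(self, p: int) -> np.ndarray:
        if self.pi is not None:
            pi = np.broadcast_to(np.asarray(self.pi, float), (p,)).copy()
        else:
            pi = np.full(p, min(self.expected_model_size / max(p, 1), 1.0))
        if np.any((pi < 0) | (pi > 1)):
            raise ConfigError("prior inclusion probabilities must lie in [0, 1]")
        return pi


class SpikeSlabSampler:
    """Gibbs sampler for (gamma, beta, sigma2) given a fixed design.

    Precomputes the cross-products so that one full scan costs one small
    Cholesky factorisation per candidate column (the active set stays
    small under a sparse prior).
    """

    def __init__(self, X: np.ndarray, prior: SpikeSlabPrior, s2_default: float):
        X = np.atleast_2d(np.asarray(X, float))
        self.X = X
        self.n, self.p = X.shape
        self.prior = prior
        self.pi = prior.inclusion_probs(self.p)
        XtX = X.T @ X
        w = prior.diagonal_weight
        dg = np.diag(np.diagonal(XtX))
        self.V0inv = (prior.kappa / max(self.n, 1)) * (w * XtX + (1.0 - w) * dg)
        if self.p and not np.all(np.diagonal(self.V0inv) > 0):
            raise NumericError(
                "singular slab precision (a design column has zero sum of "
                "squares); raise kappa or drop constant columns"
            )
        self.XtX = XtX
        self.nu = prior.nu
        self.s2 = prior.s2 if prior.s2 is not None else s2_default
        self.ss0 = self.nu * self.s2
        # log prior odds of inclusion per column
        with np.errstate(divide="ignore"):
            self.log_odds_prior = np.log(self.pi) - np.log1p(-self.pi)

    def _log_marginal(self, idx: np.ndarray, Xtz: np.ndarray, ztz: float,
                      need_beta: bool = False):
        """Log marginal likelihood of z under the subset ``idx`` (prior terms
        on gamma excluded; constants shared across subsets dropped)."""
        if idx.size == 0:
            ssn = self.ss0 + ztz
            return -0.5 * (self.nu + self.n) * np.log(ssn), ssn, None, None
        rows = idx[:, None]
        V0 = self.V0inv[rows, idx]
        Vninv = self.XtX[rows, idx] + V0
        Ln, info_n = dpotrf(Vninv, lower=1, overwrite_a=1)
        L0, info_0 = dpotrf(V0, lower=1, overwrite_a=1)
        if info_n or info_0:
            raise NumericError(
                "singular slab precision during Gibbs scan; raise kappa"
            )
        b = Xtz[idx]
        u, _ = dtrtrs(Ln, b, lower=1)
        ssn = self.ss0 + ztz - u @ u
        ssn = max(ssn, 1e-300)
        logdet_ratio = (np.log(np.diagonal(L0)).sum()
                        - np.log(np.diagonal(Ln)).sum())
        lm = logdet_ratio - 0.5 * (self.nu + self.n) * np.log(ssn)
        btilde = dtrtrs(Ln, u, lower=1, trans=1)[0] if need_beta else None
        return lm, ssn, btilde, Ln

    def draw(self, z: np.ndarray, gamma: np.ndarray, rng: np.random.Generator):
        """One Gibbs scan over gamma, then beta | gamma and sigma2 | gamma."""
        z = np.asarray(z, float).ravel()
        Xtz = self.X.T @ z if self.p else np.zeros(0)
        ztz = float(z @ z)
        gamma = gamma.copy()
        idx = np.flatnonzero(gamma)
        cur_lm, _, _, _ = self._log_marginal(idx, Xtz, ztz)
        for j in rng.permutation(self.p):
            if self.pi[j] == 0.0:
                gamma[j] = False
                continue
            if self.pi[j] == 1.0:
                if not gamma[j]:
                    gamma[j] = True
                    cur_lm, _, _, _ = self._log_marginal(
                        np.flatnonzero(gamma), Xtz, ztz)
                continue
            flipped = gamma.copy()
            flipped[j] = ~flipped[j]
            lm_flip, _, _, _ = self._log_marginal(
                np.flatnonzero(flipped), Xtz, ztz)
            # log odds of gamma_j = 1 versus 0, all else fixed
            if gamma[j]:
                log_odds = self.log_odds_prior[j] + cur_lm - lm_flip
            else:
                log_odds = self.log_odds_prior[j] + lm_flip - cur_lm
            p_incl = 1.0 / (1.0 + np.exp(-log_odds))
            new_val = rng.random() < p_incl
            if new_val != gamma[j]:
                gamma[j] = new_val
                cur_lm = lm_flip
        idx = np.flatnonzero(gamma)
        _, ssn, btilde, Ln = self._log_marginal(idx, Xtz, ztz, need_beta=True)
        sigma2 = ssn / (2.0 * rng.gamma(0.5 * (self.nu + self.n), 1.0))
        beta = np.zeros(self.p)
        if idx.size:
            u = rng.standard_normal(idx.size)
            beta[idx] = btilde + np.sqrt(sigma2) * dtrtrs(
                Ln, u, lower=1, trans=1)[0]
        return gamma, beta, sigma2


def sample_spike_slab(
    y_minus_state: np.ndarray,
    X: np.ndarray,
    prior: SpikeSlabPrior,
    rng: np.random.Generator,
    gamma: np.ndarray | None = None,
):
    """One spike-and-slab Gibbs scan on the regression residual series.

    Convenience wrapper over :class:`SpikeSlabSampler` for one-off scans;
    the iterative sampler in :func:`fit_bsts` reuses one sampler instance.
    """
    z = np.asarray(y_minus_state, float).ravel()
    sampler = SpikeSlabSampler(X, prior, s2_default=0.5 * max(z.var(), 1e-12))
    if gamma is None:
        gamma = np.zeros(sampler.p, dtype=bool)
    return sampler.draw(z, gamma, rng)


# ---------------------------------------------------------------------------
# the Gibbs sampler

@dataclass
class PosteriorDraws:
    """Retained MCMC draws of all unknowns plus reproducibility metadata."""

    states: np.ndarray           # (m, T, d)
    sigma2: np.ndarray           # (m,)
    variances: dict[str, np.ndarray]  # component name -> (m,)
    gamma: np.ndarray            # (m, p) bool
    beta: np.ndarray             # (m, p)
    n_iter: int
    n_burn: int
    seed: object = None
    components: tuple = ()
    season_period: int = 0

    @property
    def n_kept(self) -> int:
        return self.states.shape[0]

    def inclusion_probs(self) -> np.ndarray:
        if self.gamma.size == 0:
            return np.zeros(self.gamma.shape[1])
        return self.gamma.mean(axis=0)


# Prior sd guesses for the component disturbances, as fractions of sd(y).
# The trend must move slowly for the counterfactual to be informative at
# multi-month horizons (the covariates, not the trend, should explain the
# medium-run movement), so the trend priors are informative: a guess of
# 0.01 sd(y) for the level and 0.001 sd(y) for the slope, each worth
# ``variance_prior_df`` observations.  This follows the convention
# popularised by the widely used R implementations of this model family.
_VAR_PRIOR_SD_FRACTION = {"level": 0.01, "slope": 0.001, "seasonal": 0.01}


def fit_bsts(
    y_pre: np.ndarray,
    X_pre: np.ndarray | None = None,
    prior: SpikeSlabPrior | None = None,
    n_iter: int = 10000,
    n_burn: int | None = None,
    rng: np.random.Generator | int | None = None,
    components: Sequence[str] = ("trend", "seasonal"),
    season_period: int = 12,
    min_pre_months: int = 24,
    variance_prior_df: float = 32.0,
    init_scale: float = 1e6,
) -> tuple[PosteriorDraws, StateSpaceModel]:
    """Fit the structural model to the pre-intervention log series by MCMC.

    Blocked Gibbs cycle per iteration: simulation-smoother draw of the state
    path given (variances, beta, sigma2); inverse-gamma draws of the trend
    and seasonal disturbance variances given the states; spike-and-slab
    draw of (gamma, beta, sigma2) on the observation residual.  Burn-in
    defaults to 10% of ``n_iter``.

    Returns the retained draws and the model skeleton (for prediction).
    """
    y = np.asarray(y_pre, float).ravel()
    n = y.size
    if n < min_pre_months:
        raise SamplerError(
            f"pre-period has {n} months; at least {min_pre_months} required"
        )
    if n_burn is None:
        n_burn = n_iter // 10
    if not 0 <= n_burn < n_iter:
        raise ConfigError("n_burn must satisfy 0 <= n_burn < n_iter")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    has_X = X_pre is not None and np.size(X_pre) > 0
    if has_X:
        X = np.atleast_2d(np.asarray(X_pre, float))
        if X.shape[0] != n:
            raise ConfigError("X_pre and y_pre lengths differ")
        p = X.shape[1]
    else:
        X = np.zeros((n, 0))
        p = 0

    obs = y[~np.isnan(y)]
    y_var = max(obs.var(), 1e-12)

    model = build_model(components=components, s=season_period, n_covariates=p,
                        init_var=init_scale * y_var)
    model.a1[0] = obs[0] if "trend" in components else 0.0
    active_vars = [k for k in ("level", "slope", "seasonal")
                   if k in model._dist_index]

    nu0 = variance_prior_df
    guess = {k: (_VAR_PRIOR_SD_FRACTION[k] ** 2) * y_var for k in active_vars}
    var_prior = {k: (0.5 * nu0, 0.5 * nu0 * guess[k]) for k in active_vars}
    # start the chain at a data-scaled value so burn-in is short even when
    # the prior guess is far below the likelihood's preferred scale
    dy_var = max(np.diff(obs).var(), 1e-12) if obs.size > 2 else y_var
    comp_var = {k: max(guess[k], 0.05 * dy_var) for k in active_vars}
    sigma2 = 0.5 * y_var
    if prior is None:
        prior = SpikeSlabPrior()
    slab = SpikeSlabSampler(X, prior, s2_default=0.5 * y_var) if p else None
    gamma = np.zeros(p, dtype=bool)
    beta = np.zeros(p)
    ss_sigma_prior = (0.5 * prior.nu,
                      0.5 * prior.nu * (prior.s2 if prior.s2 is not None
                                        else 0.5 * y_var))

    m = n_iter - n_burn
    keep_states = np.empty((m, n, model.d))
    keep_sigma2 = np.empty(m)
    keep_vars = {k: np.empty(m) for k in active_vars}
    keep_gamma = np.zeros((m, p), dtype=bool)
    keep_beta = np.zeros((m, p))

    tr = model.blocks.get("trend")
    se = model.blocks.get("seasonal")
    for it in range(n_iter):
        model.sigma2 = sigma2
        model.set_variances(**comp_var)
        resid = y - X @ beta if p else y
        alpha = simulation_smoother(model, resid, rng)

        # component variances | state path (conjugate inverse gamma)
        for k in active_vars:
            a0, b0 = var_prior[k]
            if k == "level":
                e = alpha[1:, tr.start] - alpha[:-1, tr.start] - alpha[:-1, tr.start + 1]
            elif k == "slope":
                e = alpha[1:, tr.start + 1] - alpha[:-1, tr.start + 1]
            else:
                e = alpha[1:, se.start] + alpha[:-1, se].sum(axis=1)
            shape = a0 + 0.5 * e.size
            scale = b0 + 0.5 * float(e @ e)
            comp_var[k] = scale / rng.gamma(shape, 1.0)

        # regression + observation variance | states
        signal = alpha @ model.Z
        z = y - signal
        zobs = z[~np.isnan(z)]
        if p:
            if np.isnan(z).any():
                raise SamplerError(
                    "missing target values are not supported with covariates"
                )
            gamma, beta, sigma2 = slab.draw(z, gamma, rng)
        else:
            a0, b0 = ss_sigma_prior
            shape = a0 + 0.5 * zobs.size
            scale = b0 + 0.5 * float(zobs @ zobs)
            sigma2 = scale / rng.gamma(shape, 1.0)

        if not (np.isfinite(sigma2) and all(np.isfinite(v) for v in comp_var.values())):
            raise SamplerError(f"non-finite variance draw at iteration {it}")
        if it >= n_burn:
            j = it - n_burn
            keep_states[j] = alpha
            keep_sigma2[j] = sigma2
            for k in active_vars:
                keep_vars[k][j] = comp_var[k]
            if p:
                keep_gamma[j] = gamma
                keep_beta[j] = beta

    draws = PosteriorDraws(
        states=keep_states, sigma2=keep_sigma2, variances=keep_vars,
        gamma=keep_gamma, beta=keep_beta, n_iter=n_iter, n_burn=n_burn,
        seed=None, components=tuple(components), season_period=season_period,
    )
    return draws, model


def posterior_predict(
    draws: PosteriorDraws,
    model: StateSpaceModel,
    X_post: np.ndarray | None,
    horizon: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample posterior-predictive paths for the next ``horizon`` months.

    For each retained draw the state is propagated forward from its final
    in-sample value through the state equation with fresh disturbances, the
    regression mean shift from the observed post-period covariates is
    added, and observation noise is applied.  Returns an
    ``(n_draws, horizon)`` matrix on the log scale.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    m = draws.n_kept
    p = draws.beta.shape[1]
    if p:
        if X_post is None:
            raise ConfigError("X_post required when the model has covariates")
        X_post = np.atleast_2d(np.asarray(X_post, float))
        if X_post.shape[0] != horizon:
            raise ConfigError(
                f"X_post has {X_post.shape[0]} rows but horizon={horizon}"
            )
        reg = draws.beta @ X_post.T  # (m, horizon)
    else:
        reg = np.zeros((m, horizon))

    d, q = model.d, model.q
    # per-draw disturbance sds in Q-diagonal order
    qsd = np.zeros((m, q))
    for name, pos in model._dist_index.items():
        qsd[:, pos] = np.sqrt(draws.variances[name])
    alpha = draws.states[:, -1, :].copy()  # (m, d)
    paths = np.empty((m, horizon))
    Tm, Rm, Z = model.T, model.R, model.Z
    sig = np.sqrt(draws.sigma2)
    for h in range(horizon):
        eta = rng.standard_normal((m, q)) * qsd
        alpha = alpha @ Tm.T + eta @ Rm.T
        eps = rng.standard_normal(m) * sig
        paths[:, h] = alpha @ Z + reg[:, h] + eps
    return paths


def one_step_predictions(
    model: StateSpaceModel,
    y: np.ndarray,
    X: np.ndarray | None,
    beta: np.ndarray,
    variances: dict[str, float],
    sigma2: float,
):
    """In-sample one-step-ahead predictive means and sds at fixed parameters.

    Used for pre-period validation: at the posterior means of (variances,
    beta, sigma2), the filter's one-step prediction of y_t given y_{1:t-1}
    has mean Z a_t + x_t beta and variance F_t.
    """
    y = np.asarray(y, float).ravel()
    work = StateSpaceModel(
        Z=model.Z, T=model.T, R=model.R, Q=model.Q.copy(), sigma2=sigma2,
        a1=model.a1, P1=model.P1,
    )
    work._dist_index = model._dist_index
    work.set_variances(**variances)
    shift = X @ beta if (X is not None and np.size(beta)) else np.zeros_like(y)
    fr = kalman_filter(work, y - shift)
    mean = fr.a @ model.Z + shift
    var = np.array([
        float(model.Z @ fr.P[t] @ model.Z + sigma2) for t in range(y.size)
    ])
    return mean, np.sqrt(var)


# ---------------------------------------------------------------------------
# estimator facade

class BSTSModel(BaseEstimator):
    """Structural time-series regression with spike-and-slab selection.

    scikit-learn style estimator over :func:`fit_bsts`: ``fit(X, y)`` runs
    the Gibbs sampler on the (log-scale) target ``y`` with design ``X``
    (``X=None`` for a pure trend + seasonal model); ``sample_predictive``
    draws posterior-predictive paths for out-of-sample months.

    Parameters
    ----------
    components : tuple of str
        Structural blocks, subset of {"trend", "seasonal"}.
    season_period : int
        Seasonal period (12 for monthly data).
    expected_model_size : float
        Prior expected number of included covariates.
    kappa : float
        Slab information weight (prior observations worth of precision).
    n_iter, n_burn : int
        MCMC iterations and burn-in (burn-in defaults to 10%).
    random_state : int or numpy Generator
        Seeds every draw; identical seeds give identical posteriors.
    """

    def __init__(
        self,
        components: tuple = ("trend", "seasonal"),
        season_period: int = 12,
        expected_model_size: float = 5.0,
        kappa: float = 1.0,
        prior_df: float = 0.01,
        n_iter: int = 2000,
        n_burn: int | None = None,
        min_pre_months: int = 24,
        variance_prior_df: float = 32.0,
        init_scale: float = 1e6,
        random_state=None,
    ):
        self.components = components
        self.season_period = season_period
        self.expected_model_size = expected_model_size
        self.kappa = kappa
        self.prior_df = prior_df
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.min_pre_months = min_pre_months
        self.variance_prior_df = variance_prior_df
        self.init_scale = init_scale
        self.random_state = random_state

    def _rng(self):
        if isinstance(self.random_state, np.random.Generator):
            return self.random_state
        return np.random.default_rng(self.random_state)

    def fit(self, X, y):
        y = np.asarray(y, float).ravel()
        prior = SpikeSlabPrior(
            expected_model_size=self.expected_model_size,
            kappa=self.kappa, nu=self.prior_df,
        )
        self.draws_, self.model_ = fit_bsts(
            y, X, prior=prior, n_iter=self.n_iter, n_burn=self.n_burn,
            rng=self._rng(), components=self.components,
            season_period=self.season_period,
            min_pre_months=self.min_pre_months,
            variance_prior_df=self.variance_prior_df,
            init_scale=self.init_scale,
        )
        self.n_features_in_ = 0 if X is None else np.atleast_2d(X).shape[1]
        self.inclusion_probs_ = self.draws_.inclusion_probs()
        self.coef_ = (self.draws_.beta.mean(axis=0)
                      if self.n_features_in_ else np.zeros(0))
        self.y_train_ = y
        self.X_train_ = None if X is None else np.atleast_2d(np.asarray(X, float))
        return self

    def sample_predictive(self, X, horizon=None, random_state=None):
        """Posterior-predictive draws, shape (n_draws, horizon), log scale."""
        if horizon is None:
            horizon = 0 if X is None else np.atleast_2d(X).shape[0]
        rng = (random_state if isinstance(random_state, np.random.Generator)
               else np.random.default_rng(random_state))
        return posterior_predict(self.draws_, self.model_, X, horizon, rng)

    def predict(self, X, horizon=None, random_state=0):
        """Posterior-predictive mean per out-of-sample month (log scale)."""
        return self.sample_predictive(X, horizon, random_state).mean(axis=0)

    def one_step_ahead(self):
        """Pre-period one-step-ahead (mean, sd) at posterior-mean parameters."""
        variances = {k: float(v.mean()) for k, v in self.draws_.variances.items()}
        return one_step_predictions(
            self.model_, self.y_train_, self.X_train_, self.coef_,
            variances, float(self.draws_.sigma2.mean()),
        )
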