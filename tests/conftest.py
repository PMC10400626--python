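"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import flowimpact as fi


def brute_force_loglik(model, y):
    """Joint-Gaussian log-density of the observed entries of y.

    Independent oracle for the Kalman filter: builds the full T x T
    covariance of the observations by propagating the state equations,
    then evaluates the multivariate normal density directly (marginalizing
    missing entries).  O(T^3) — small instances only.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    d = model.d
    RQR = model.R @ model.Q @ model.R.T
    Ea = np.empty((n, d))
    Ea[0] = model.a1
    for t in range(1, n):
        Ea[t] = model.T @ Ea[t - 1]
    V = np.empty((n, n, d, d))
    V[0, 0] = model.P1
    for t in range(1, n):
        V[t, t] = model.T @ V[t - 1, t - 1] @ model.T.T + RQR
    for s in range(n):
        for t in range(s + 1, n):
            V[s, t] = V[s, t - 1] @ model.T.T
            V[t, s] = V[s, t].T
    Z = model.Z
    mu = Ea @ Z
    S = np.einsum("i,stij,j->st", Z, V, Z) + np.eye(n) * model.sigma2
    obs = ~np.isnan(y)
    return multivariate_normal(
        mu[obs], S[np.ix_(obs, obs)], allow_singular=True
    ).logpdf(y[obs])


def random_proper_model(rng, d_max=3):
    """A random, numerically well-behaved state-space model."""
    d = int(rng.integers(1, d_max + 1))
    q = int(rng.integers(1, d + 1))
    return fi.StateSpaceModel(
        Z=rng.normal(0, 1, d),
        T=rng.normal(0, 0.5, (d, d)),
        R=rng.normal(0, 1, (d, q)),
        Q=np.diag(rng.uniform(0.1, 1.0, q)),
        sigma2=float(rng.uniform(0.2, 2.0)),
        a1=rng.normal(0, 1, d),
        P1=np.eye(d) * float(rng.uniform(0.5, 2.0)),
    )


def local_level_model(level_var=0.5, sigma2=1.0, a1=0.0, P1=2.0):
    return fi.StateSpaceModel(
        Z=[1.0], T=[[1.0]], R=[[1.0]], Q=[[level_var]],
        sigma2=sigma2, a1=[a1], P1=[[P1]],
    )


def month_index(n, start="2011-01-01"):
    return pd.date_range(start, periods=n, freq="MS")


def make_flow(attempts, death_share=0.04, pushback_share=0.06, start="2011-01-01"):
    """Deterministic FlowSeries with the requested monthly totals."""
    y = np.asarray(attempts, dtype=np.int64)
    d = np.round(y * death_share).astype(np.int64)
    p = np.round(y * pushback_share).astype(np.int64)
    a = y - d - p
    idx = month_index(len(y), start)
    return fi.assemble_crossing_attempts(
        pd.Series(a, index=idx), pd.Series(p, index=idx), pd.Series(d, index=idx)
    )


@pytest.fixture(scope="session")
def effect_scenario():
    """84-month scenario with a 1.5x multiplicative effect from month 60."""
    cfg = fi.ScenarioConfig(
        n_months=84, n_covariates=10, n_active=5,
        beta_active=(0.3, -0.25, 0.2, 0.2, -0.15),
        interventions=((60, 1.5),), seed=11,
    )
    flow, panel, truth = fi.generate_scenario(cfg)
    return cfg, flow, panel, truth


@pytest.fixture(scope="session")
def null_scenario():
    """72-month scenario with no intervention effect."""
    cfg = fi.ScenarioConfig(
        n_months=72, n_covariates=10, n_active=5,
        beta_active=(0.3, -0.25, 0.2, 0.2, -0.15), seed=4,
    )
    flow, panel, truth = fi.generate_scenario(cfg)
    return cfg, flow, panel, truth
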