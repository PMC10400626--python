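"""Hot inner loops of the state-space recursions.

The Gibbs sampler runs one Kalman filter + smoother pass per MCMC
iteration, so these sequential recursions are written as tight loops and
JIT-compiled with numba when available; the same functions run as plain
numpy if numba is absent (identical results, just slower).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def filter_core(y, Z, T, RQR, sigma2, a1, P1):
    """Kalman filter recursions; NaN observations skip the update step.

    Returns predicted/filtered means and covariances, prediction errors
    and variances, the log-likelihood and a status flag (0 on a
    non-positive prediction variance).
    """
    n = y.shape[0]
    d = a1.shape[0]
    a = np.empty((n, d))
    P = np.empty((n, d, d))
    att = np.empty((n, d))
    Ptt = np.empty((n, d, d))
    v = np.full(n, np.nan)
    F = np.full(n, np.nan)
    loglik = 0.0
    a_t = a1.copy()
    P_t = P1.copy()
    LOG2PI = 1.8378770664093453
    ok = 1
    for t in range(n):
        a[t] = a_t
        P[t] = P_t
        yt = y[t]
        if not np.isnan(yt):
            PZ = P_t @ Z
            F_t = Z @ PZ + sigma2
            if F_t <= 0.0 or not np.isfinite(F_t):
                ok = 0
                break
            v_t = yt - Z @ a_t
            v[t] = v_t
            F[t] = F_t
            K = PZ / F_t
            att[t] = a_t + K * v_t
            Ptt[t] = P_t - np.outer(K, PZ)
            loglik += -0.5 * (LOG2PI + np.log(F_t) + v_t * v_t / F_t)
        else:
            att[t] = a_t
            Ptt[t] = P_t
        a_t = T @ att[t]
        Pn = T @ Ptt[t] @ T.T + RQR
        P_t = 0.5 * (Pn + Pn.T)
    return a, P, att, Ptt, v, F, loglik, ok


@njit(cache=False)
def smoother_core(a, P, v, F, obs, Z, T):
    """Backward disturbance-smoother pass: smoothed state means only."""
    n, d = a.shape
    alphahat = np.empty((n, d))
    r = np.zeros(d)
    for t in range(n - 1, -1, -1):
        if obs[t]:
            Finv = 1.0 / F[t]
            K = T @ (P[t] @ Z) * Finv
            # r_{t-1} = Z v/F + L' r with L = T - K Z'
            r = Z * (v[t] * Finv) + T.T @ r - Z * (K @ r)
        else:
            r = T.T @ r
        alphahat[t] = a[t] + P[t] @ r
    return alphahat


@njit(cache=False)
def simulate_states_core(alpha0, T, R, eta):
    """Propagate one unconditional state path given pre-drawn disturbances."""
    n = eta.shape[0]
    d = alpha0.shape[0]
    alpha = np.empty((n, d))
    a_t = alpha0.copy()
    for t in range(n):
        alpha[t] = a_t
        a_t = T @ a_t + R @ eta[t]
    return alpha
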