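"""Compiled inner loop of the log-linear recursive filter.

The per-bin Newton mode search dominates the cost of everything built on
the filter (EM fits, information criteria, surrogate Bayes-factor tests),
so the forward pass specialized to the log-linear observation model is
implemented here as a numba kernel.  The pure-numpy implementation in
``ssll.statespace`` remains the reference path and is used automatically
when numba is unavailable or for non-log-linear observation models; both
paths implement the identical recursion.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


LOG_2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def _chol_lower(S):
    """Lower Cholesky factor with an explicit success flag (no exceptions)."""
    d = S.shape[0]
    L = np.zeros((d, d))
    for j in range(d):
        acc = S[j, j]
        for k in range(j):
            acc -= L[j, k] * L[j, k]
        if acc <= 0.0:
            return L, False
        L[j, j] = math.sqrt(acc)
        for i in range(j + 1, d):
            acc = S[i, j]
            for k in range(j):
                acc -= L[i, k] * L[j, k]
            L[i, j] = acc / L[j, j]
    return L, True


@njit(cache=True)
def _sym_inv_logdet(M, jitter):
    d = M.shape[0]
    S = 0.5 * (M + M.T)
    L, ok = _chol_lower(S)
    if not ok:
        L, ok = _chol_lower(S + jitter * np.eye(d))
        if not ok:  # caller treats non-finite logdet as failure
            return np.eye(d), math.nan
    logdet = 0.0
    for i in range(d):
        logdet += 2.0 * math.log(L[i, i])
    # invert L by forward substitution, then S^-1 = L^-T L^-1
    Linv = np.zeros((d, d))
    for i in range(d):
        Linv[i, i] = 1.0 / L[i, i]
        for j in range(i):
            acc = 0.0
            for k in range(j, i):
                acc -= L[i, k] * Linv[k, j]
            Linv[i, j] = acc / L[i, i]
    return Linv.T @ Linv, logdet


@njit(cache=True)
def ll_filter_pass(y, R, F, A, Q, mu, Sigma, alpha0, tol, max_newton):
    """Forward Laplace filter for the log-linear observation model.

    Returns (pred_mean, pred_cov, filt_mean, filt_cov, logml, status) with
    status 0 on success, 1 + bin index on Newton failure.
    """
    T, d = y.shape
    n_pat = F.shape[0]
    Ft = np.ascontiguousarray(F.T)
    pred_mean = np.empty((T, d))
    pred_cov = np.empty((T, d, d))
    filt_mean = np.empty((T, d))
    filt_cov = np.empty((T, d, d))
    logml = 0.0
    m = mu.copy()
    W = 0.5 * (Sigma + Sigma.T)
    for t in range(T):
        if t > 0:
            m = A @ filt_mean[t - 1]
            W = A @ filt_cov[t - 1] @ A.T + Q
            W = 0.5 * (W + W.T)
        pred_mean[t] = m
        pred_cov[t] = W
        prec, logdet_pred = _sym_inv_logdet(W, 1e-10)
        if math.isnan(logdet_pred):
            return pred_mean, pred_cov, filt_mean, filt_cov, logml, t + 1
        yt = y[t]
        theta = m.copy()
        lp = -1e300
        have_lp = False
        converged = False
        H = np.empty((d, d))
        for _ in range(max_newton):
            s = F @ theta
            mx = s.max()
            p = np.exp(s - mx)
            Z = p.sum()
            p = p / Z
            eta = Ft @ p
            G = (Ft * p) @ F - np.outer(eta, eta)
            grad = R * (yt - eta) - prec @ (theta - m)
            H = R * G + prec
            step = np.linalg.solve(H, grad)
            if not have_lp:
                psi = mx + math.log(Z)
                r0 = theta - m
                lp = R * (theta @ yt - psi) - 0.5 * r0 @ prec @ r0
                have_lp = True
            alpha = alpha0
            accepted = False
            cand = theta
            clp = lp
            for _ls in range(50):
                cand = theta + alpha * step
                s2 = F @ cand
                mx2 = s2.max()
                psi2 = mx2 + math.log(np.exp(s2 - mx2).sum())
                r = cand - m
                clp = R * (cand @ yt - psi2) - 0.5 * r @ prec @ r
                if clp >= lp - 1e-12:
                    accepted = True
                    break
                alpha *= 0.5
            theta = cand
            lp = clp
            if accepted and np.max(np.abs(alpha * step)) < tol:
                converged = True
                break
        if not converged:
            return pred_mean, pred_cov, filt_mean, filt_cov, logml, t + 1
        # final Hessian at the mode
        s = F @ theta
        mx = s.max()
        p = np.exp(s - mx)
        Z = p.sum()
        p = p / Z
        eta = Ft @ p
        G = (Ft * p) @ F - np.outer(eta, eta)
        H = R * G + prec
        cov, logdetH = _sym_inv_logdet(H, 1e-10)
        filt_mean[t] = theta
        filt_cov[t] = cov
        psi = mx + math.log(Z)
        ll = R * (theta @ yt - psi)
        r = theta - m
        log_prior = -0.5 * (r @ prec @ r + logdet_pred + d * LOG_2PI)
        logml += ll + log_prior + 0.5 * d * LOG_2PI - 0.5 * logdetH
    return pred_mean, pred_cov, filt_mean, filt_cov, logml, 0
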