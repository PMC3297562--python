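"""Recursive Bayesian filter/smoother for state-space log-linear models.

The latent state theta_t (natural parameters of the bin-t log-linear model)
follows first-order linear-Gaussian dynamics

    theta_t = A theta_{t-1} + xi_t,   xi_t ~ N(0, Q),   theta_1 ~ N(mu, Sigma),

observed through R independent binary spike patterns per bin whose
log-likelihood is ``R * (theta' y_t - psi(theta))`` with y_t the observed
synchrony rates.  The posterior of theta_t is approximated as Gaussian at
every step (Laplace method): the filter mode is found by Newton iterations
on the log-concave posterior, the covariance from its Hessian, and a
fixed-interval (RTS-form) smoother runs backwards.  The per-bin Laplace
integrals accumulate into an approximate log marginal likelihood used by
the EM algorithm and the information criteria.

An observation model with a Gaussian likelihood is also provided; with it
the filter and smoother reduce exactly to the Kalman filter and RTS
smoother, which serves as an independent oracle in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as _KERNELS
from .loglinear import MultiIndexSet, feature_matrix
from .spikedata import SynchronyRates

LOG_2PI = math.log(2.0 * math.pi)

__all__ = [
    "StateHyperParams",
    "GaussianBelief",
    "PosteriorTrajectory",
    "FilterOptions",
    "FilterError",
    "LogLinearObservations",
    "GaussianObservations",
    "predict",
    "filter_update",
    "smooth",
    "lag_one_covariances",
    "filter_pass",
    "run_estep",
]


class FilterError(RuntimeError):
    """Numerical failure inside the recursive filter."""


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def _chol_inverse(M: np.ndarray, jitter: float = 1e-10):
    """(inverse, log-determinant) via Cholesky, with jitter on failure."""
    M = _symmetrize(M)
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(M + jitter * np.eye(M.shape[0]))
    logdet = 2.0 * float(np.sum(np.log(np.diagonal(L))))
    Linv = np.linalg.inv(L)
    return Linv.T @ Linv, logdet


@dataclass
class StateHyperParams:
    """Hyper-parameters w = (A, Q, mu, Sigma) of the state equation."""

    transition: np.ndarray
    innovation_cov: np.ndarray
    initial_mean: np.ndarray
    initial_cov: np.ndarray
    fix_transition_identity: bool = False
    fix_innovation_zero: bool = False

    def __post_init__(self):
        self.transition = np.atleast_2d(np.asarray(self.transition, dtype=float))
        self.innovation_cov = np.atleast_2d(
            np.asarray(self.innovation_cov, dtype=float)
        )
        self.initial_mean = np.atleast_1d(np.asarray(self.initial_mean, dtype=float))
        self.initial_cov = np.atleast_2d(np.asarray(self.initial_cov, dtype=float))
        d = self.initial_mean.shape[0]
        for name, M in (("transition", self.transition),
                        ("innovation_cov", self.innovation_cov),
                        ("initial_cov", self.initial_cov)):
            if M.shape != (d, d):
                raise ValueError(f"{name} must be {d}x{d}, got {M.shape}")
        for name, M in (("innovation_cov", self.innovation_cov),
                        ("initial_cov", self.initial_cov)):
            if np.max(np.abs(M - M.T)) > 1e-10:
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(_symmetrize(M))) < -1e-12:
                raise ValueError(f"{name} must be positive semidefinite")

    @property
    def dim(self) -> int:
        return self.initial_mean.shape[0]

    @classmethod
    def default(cls, d: int, state_model: str = "random_walk",
                initial_mean=None, q_scale: float = 0.01) -> "StateHyperParams":
        """Scale-free starting point: A = I, Q = q_scale*I, Sigma = I."""
        mu = np.zeros(d) if initial_mean is None else np.asarray(initial_mean, float)
        if state_model == "static":
            return cls(np.eye(d), np.zeros((d, d)), mu, np.eye(d),
                       fix_transition_identity=True, fix_innovation_zero=True)
        if state_model == "random_walk":
            return cls(np.eye(d), q_scale * np.eye(d), mu, np.eye(d),
                       fix_transition_identity=True)
        if state_model == "ar1":
            return cls(np.eye(d), q_scale * np.eye(d), mu, np.eye(d))
        raise ValueError(f"unknown state_model {state_model!r}")


@dataclass
class GaussianBelief:
    """Gaussian approximation N(mean, cov) of a state posterior."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = _symmetrize(np.atleast_2d(np.asarray(self.cov, dtype=float)))


@dataclass
class FilterOptions:
    """Numerical knobs of the per-bin Newton mode search."""

    learning_rate: float = 1.0   # alpha; smaller values for large populations
    tol: float = 1e-10           # per-element increment threshold
    max_iter: int = 100
    fast_approx: bool = False    # single Newton step from the prediction mean


class LogLinearObservations:
    """Binary-pattern likelihood summarized by per-bin synchrony rates."""

    def __init__(self, rates: SynchronyRates, n_trials: int):
        if n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        self.index_set = rates.index_set
        self.y = np.ascontiguousarray(rates.rates)
        self.R = int(n_trials)
        self.F = feature_matrix(rates.index_set)
        self.Ft = np.ascontiguousarray(self.F.T)

    @property
    def n_bins(self) -> int:
        return self.y.shape[0]

    def _probs(self, theta):
        s = self.F @ theta
        s -= s.max()
        p = np.exp(s)
        p /= p.sum()
        return p

    def eta(self, theta):
        return self.Ft @ self._probs(theta)

    def loglik(self, t, theta):
        s = self.F @ theta
        m = s.max()
        psi = m + math.log(np.exp(s - m).sum())
        return self.R * (theta @ self.y[t] - psi)

    def grad_neghess(self, t, theta):
        p = self._probs(theta)
        eta = self.Ft @ p
        G = (self.Ft * p) @ self.F - np.outer(eta, eta)
        return self.R * (self.y[t] - eta), self.R * G


class GaussianObservations:
    """Linear-Gaussian likelihood y_t ~ N(H theta_t, S); Kalman oracle mode."""

    def __init__(self, y: np.ndarray, H: np.ndarray, S: np.ndarray):
        self.y = np.atleast_2d(np.asarray(y, dtype=float))
        self.H = np.atleast_2d(np.asarray(H, dtype=float))
        self.S = np.atleast_2d(np.asarray(S, dtype=float))
        self.S_inv, self.S_logdet = _chol_inverse(self.S)
        self._neghess = self.H.T @ self.S_inv @ self.H

    @property
    def n_bins(self) -> int:
        return self.y.shape[0]

    def loglik(self, t, theta):
        r = self.y[t] - self.H @ theta
        k = self.y.shape[1]
        return -0.5 * (r @ self.S_inv @ r + self.S_logdet + k * LOG_2PI)

    def grad_neghess(self, t, theta):
        g = self.H.T @ (self.S_inv @ (self.y[t] - self.H @ theta))
        return g, self._neghess


def predict(prev_filter: GaussianBelief, hyper: StateHyperParams) -> GaussianBelief:
    """One-step prediction: mean = A m, cov = A W A' + Q (Chapman-Kolmogorov)."""
    A = hyper.transition
    mean = A @ prev_filter.mean
    cov = _symmetrize(A @ prev_filter.cov @ A.T + hyper.innovation_cov)
    return GaussianBelief(mean, cov)


def _newton_mode(pred_mean, pred_prec, obs, t, options):
    """Newton mode search on the log-concave per-bin posterior.

    Returns (mode, neghess_at_mode).  Satisfies the nonlinear stationarity
    condition theta = theta_pred + W_pred * grad_loglik(theta) at the mode.
    """
    theta = pred_mean.copy()
    lp = None
    for _ in range(1 if options.fast_approx else options.max_iter):
        g_obs, H_obs = obs.grad_neghess(t, theta)
        grad = g_obs - pred_prec @ (theta - pred_mean)
        H = H_obs + pred_prec
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise FilterError(f"singular filter Hessian at bin {t}: {exc}") from exc
        if options.fast_approx:
            theta = theta + options.learning_rate * step
            return theta, obs.grad_neghess(t, theta)[1] + pred_prec
        alpha = options.learning_rate
        if lp is None:
            r = theta - pred_mean
            lp = obs.loglik(t, theta) - 0.5 * r @ pred_prec @ r
        accepted = False
        for _ in range(50):
            cand = theta + alpha * step
            r = cand - pred_mean
            cand_lp = obs.loglik(t, cand) - 0.5 * r @ pred_prec @ r
            if cand_lp >= lp - 1e-12:
                accepted = True
                break
            alpha *= 0.5
        theta, lp = cand, cand_lp
        if accepted and np.max(np.abs(alpha * step)) < options.tol:
            return theta, obs.grad_neghess(t, theta)[1] + pred_prec
    g_obs, _ = obs.grad_neghess(t, theta)
    resid = float(np.max(np.abs(g_obs - pred_prec @ (theta - pred_mean))))
    raise FilterError(
        f"filter Newton did not converge at bin {t} (gradient norm {resid:.3g})"
    )


def filter_update(pred: GaussianBelief, obs, t: int,
                  options: FilterOptions | None = None) -> GaussianBelief:
    """Laplace filter update: Newton mode search on the log posterior.

    The returned mean satisfies the nonlinear stationarity condition
    ``theta = theta_pred + W_pred R (y_t - eta(theta))`` (for the log-linear
    likelihood); the covariance is ``(neghess(mode) + W_pred^-1)^-1``.
    """
    options = options or FilterOptions()
    prec, _ = _chol_inverse(pred.cov)
    mode, H = _newton_mode(pred.mean, prec, obs, t, options)
    cov, _ = _chol_inverse(H)
    return GaussianBelief(mode, cov)


def filter_pass(obs, hyper: StateHyperParams,
                options: FilterOptions | None = None):
    """Forward filter over all bins, array-valued (the package hot path).

    Returns a dict with prediction/filter means (T, d) and covariances
    (T, d, d) and the accumulated approximate log marginal likelihood.
    """
    options = options or FilterOptions()
    if (_KERNELS.HAVE_NUMBA and isinstance(obs, LogLinearObservations)
            and not options.fast_approx):
        pm, pc, fm, fc, logml, status = _KERNELS.ll_filter_pass(
            obs.y, float(obs.R), obs.F, hyper.transition,
            hyper.innovation_cov, hyper.initial_mean, hyper.initial_cov,
            options.learning_rate, options.tol, options.max_iter)
        if status != 0:
            raise FilterError(f"filter Newton did not converge at bin {status - 1}")
        if not np.isfinite(logml):
            raise FilterError("non-finite approximate log marginal likelihood")
        return {"pred_mean": pm, "pred_cov": pc, "filt_mean": fm,
                "filt_cov": fc, "log_marginal": float(logml)}
    A = hyper.transition
    Q = hyper.innovation_cov
    T = obs.n_bins
    d = hyper.dim
    pred_mean = np.empty((T, d))
    pred_cov = np.empty((T, d, d))
    filt_mean = np.empty((T, d))
    filt_cov = np.empty((T, d, d))
    logml = 0.0
    m, W = hyper.initial_mean, _symmetrize(hyper.initial_cov)
    for t in range(T):
        if t > 0:
            m = A @ filt_mean[t - 1]
            W = _symmetrize(A @ filt_cov[t - 1] @ A.T + Q)
        pred_mean[t] = m
        pred_cov[t] = W
        prec, logdet_pred = _chol_inverse(W)
        mode, H = _newton_mode(m, prec, obs, t, options)
        cov, negdet = _chol_inverse(H)          # negdet = log|H| = -log|W_filt|
        filt_mean[t] = mode
        filt_cov[t] = cov
        r = mode - m
        log_prior = -0.5 * (r @ prec @ r + logdet_pred + d * LOG_2PI)
        logml += (obs.loglik(t, mode) + log_prior
                  + 0.5 * d * LOG_2PI - 0.5 * negdet)
    if not np.isfinite(logml):
        raise FilterError("non-finite approximate log marginal likelihood")
    return {"pred_mean": pred_mean, "pred_cov": pred_cov,
            "filt_mean": filt_mean, "filt_cov": filt_cov,
            "log_marginal": float(logml)}


def smooth(predictions, filters, hyper: StateHyperParams):
    """Fixed-interval (RTS-form) smoother over the Gaussian approximations.

    Backward recursion with gain ``A_t = W_t|t A' W_t+1|t^-1``; at t = T the
    smoothed belief equals the filter belief.  Returns (smoothed, gains).
    """
    T = len(filters)
    A = hyper.transition
    smoothed = [None] * T
    gains = [None] * T
    smoothed[T - 1] = GaussianBelief(filters[T - 1].mean.copy(),
                                     filters[T - 1].cov.copy())
    for t in range(T - 2, -1, -1):
        pred_next = predictions[t + 1]
        prec_next, _ = _chol_inverse(pred_next.cov)
        At = filters[t].cov @ A.T @ prec_next
        gains[t] = At
        mean = filters[t].mean + At @ (smoothed[t + 1].mean - pred_next.mean)
        cov = filters[t].cov + At @ (smoothed[t + 1].cov - pred_next.cov) @ At.T
        smoothed[t] = GaussianBelief(mean, _symmetrize(cov))
    return smoothed, gains


def lag_one_covariances(smoothed, gains):
    """Cov(theta_t, theta_{t-1} | all data) = W_t|T A_{t-1}' per bin (t >= 1)."""
    T = len(smoothed)
    out = [None] * T
    for t in range(1, T):
        out[t] = smoothed[t].cov @ gains[t - 1].T
    return out


@dataclass
class PosteriorTrajectory:
    """Per-bin prediction/filter/smoothed beliefs plus EM-side quantities."""

    predictions: list
    filters: list
    smoothed: list
    lag_one_cov: list          # entry t: Cov(theta_t, theta_{t-1} | data); [0] is None
    smoother_gains: list       # entry t: gain A_t; [T-1] is None
    approx_log_marginal: float

    @property
    def n_bins(self) -> int:
        return len(self.filters)

    def smoothed_means(self) -> np.ndarray:
        return np.array([b.mean for b in self.smoothed])

    def smoothed_covs(self) -> np.ndarray:
        return np.array([b.cov for b in self.smoothed])

    def smoothed_vars(self) -> np.ndarray:
        return np.array([np.diag(b.cov) for b in self.smoothed])

    def credible_band(self, level: float = 0.99):
        """Pointwise central credible band (lower, upper), each (T, d)."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        m = self.smoothed_means()
        s = np.sqrt(self.smoothed_vars())
        return m - z * s, m + z * s

    def to_frame(self, index_set: MultiIndexSet, level: float = 0.99) -> pd.DataFrame:
        lo, hi = self.credible_band(level)
        m = self.smoothed_means()
        cols = {}
        for j, lab in enumerate(index_set.labels()):
            cols[f"theta_{lab}"] = m[:, j]
            cols[f"lo_{lab}"] = lo[:, j]
            cols[f"hi_{lab}"] = hi[:, j]
        df = pd.DataFrame(cols)
        df.insert(0, "bin", np.arange(self.n_bins))
        return df


def run_estep(rates_or_obs, n_trials: int | None, hyper: StateHyperParams,
              options: FilterOptions | None = None) -> PosteriorTrajectory:
    """Full forward-backward pass with Laplace log marginal likelihood.

    Parameters
    ----------
    rates_or_obs : SynchronyRates or observation model
        Synchrony rates (with ``n_trials``) or any object implementing
        ``loglik`` / ``grad_neghess`` / ``n_bins``.
    n_trials : int or None
        Number of trials R; ignored when an observation model is passed.
    hyper : StateHyperParams
    options : FilterOptions, optional

    The approximate log marginal likelihood accumulates, per bin, the
    Laplace evaluation of ``log int p(y_t | theta) p(theta | y_1:t-1) dtheta``
    at the filter mode:
    ``loglik(mode) + log N(mode; pred) + (d/2) log 2pi + 1/2 log |W_t|t|``.
    """
    if isinstance(rates_or_obs, SynchronyRates):
        obs = LogLinearObservations(rates_or_obs, n_trials)
    else:
        obs = rates_or_obs
    fp = filter_pass(obs, hyper, options)
    T = obs.n_bins
    predictions = [GaussianBelief(fp["pred_mean"][t], fp["pred_cov"][t])
                   for t in range(T)]
    filters = [GaussianBelief(fp["filt_mean"][t], fp["filt_cov"][t])
               for t in range(T)]
    smoothed, gains = smooth(predictions, filters, hyper)
    lag_one = lag_one_covariances(smoothed, gains)
    return PosteriorTrajectory(predictions, filters, smoothed, lag_one,
                               gains, fp["log_marginal"])
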