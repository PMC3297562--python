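"""EM optimization of the state-equation hyper-parameters.

The E-step (``ssll.statespace.run_estep``) produces Gaussian posteriors of
the latent natural-parameter trajectory; the M-step below maximizes the
expected complete-data log-likelihood (Q-function) in closed form over the
autoregressive matrix A, the innovation covariance Q and the initial mean
mu.  The initial covariance Sigma is held fixed.  Alternating the two steps
climbs (approximately, because of the per-bin Laplace approximation) the
log marginal likelihood of the spike data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loglinear import (ConvergenceError, ExpectationParams, build_multi_indices,
                        eta_to_theta)
from .spikedata import SynchronyRates
from .statespace import (FilterOptions, PosteriorTrajectory, StateHyperParams,
                         _symmetrize, run_estep)

__all__ = ["FitResult", "MStepOptions", "mstep", "fit_em", "initial_mean_from_rates"]

STATE_MODELS = ("static", "random_walk", "ar1")


@dataclass
class MStepOptions:
    diagonal_innovation: bool = False     # constrain Q diagonal (useful d > 20)
    update_initial_mean: bool = True
    update_initial_cov: bool = False      # alternative scheme: update Sigma, fix mu
    eigenvalue_floor: float = 0.0


@dataclass
class FitResult:
    """Converged state-space log-linear fit."""

    hyper: StateHyperParams
    trajectory: PosteriorTrajectory
    em_history: list
    n_iterations: int
    converged: bool
    order: int
    n_trials: int
    n_bins: int
    index_set: object = None
    state_model: str = "random_walk"

    @property
    def approx_log_marginal(self) -> float:
        return self.trajectory.approx_log_marginal


def _second_moments(trajectory: PosteriorTrajectory):
    """Sums of posterior second moments over transition pairs t = 2..T."""
    th = trajectory.smoothed_means()
    T, d = th.shape
    S11 = np.zeros((d, d))
    S10 = np.zeros((d, d))
    S00 = np.zeros((d, d))
    for t in range(1, T):
        S11 += trajectory.smoothed[t].cov + np.outer(th[t], th[t])
        S10 += trajectory.lag_one_cov[t] + np.outer(th[t], th[t - 1])
        S00 += trajectory.smoothed[t - 1].cov + np.outer(th[t - 1], th[t - 1])
    return S11, S10, S00


def mstep(trajectory: PosteriorTrajectory, hyper: StateHyperParams,
          options: MStepOptions | None = None) -> StateHyperParams:
    """Closed-form Q-function maximizers for (A, Q, mu); Sigma stays fixed.

    With S_ts the summed posterior second moments E[theta_t theta_s'],
    ``A = S10 S00^-1`` and ``Q = (S11 - A S10' - S10 A' + A S00 A')/(T-1)``,
    each skipped when the corresponding fix flag is set.
    """
    options = options or MStepOptions()
    T = trajectory.n_bins
    d = hyper.dim
    S11, S10, S00 = _second_moments(trajectory)
    if hyper.fix_transition_identity:
        A = np.eye(d)
    else:
        try:
            A = np.linalg.solve(S00.T, S10.T).T
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular S00 in M-step: {exc}") from exc
    if hyper.fix_innovation_zero:
        Q = np.zeros((d, d))
    elif T > 1:
        Q = (S11 - A @ S10.T - S10 @ A.T + A @ S00 @ A.T) / (T - 1)
        Q = _symmetrize(Q)
        if options.diagonal_innovation:
            Q = np.diag(np.diag(Q))
        w, V = np.linalg.eigh(Q)
        floor = max(options.eigenvalue_floor, 0.0)
        if np.min(w) < floor:
            Q = _symmetrize(V @ np.diag(np.maximum(w, floor)) @ V.T)
    else:
        Q = hyper.innovation_cov.copy()
    if options.update_initial_cov:
        # alternative initial-prior scheme: Sigma updated, mu held fixed
        mu = hyper.initial_mean.copy()
        r = trajectory.smoothed[0].mean - mu
        Sigma = _symmetrize(trajectory.smoothed[0].cov + np.outer(r, r))
    else:
        mu = (trajectory.smoothed[0].mean.copy() if options.update_initial_mean
              else hyper.initial_mean.copy())
        Sigma = hyper.initial_cov.copy()
    return StateHyperParams(
        A, Q, mu, Sigma,
        fix_transition_identity=hyper.fix_transition_identity,
        fix_innovation_zero=hyper.fix_innovation_zero,
    )


def initial_mean_from_rates(rates: SynchronyRates, shrink: float = 0.05) -> np.ndarray:
    """Data-informed initial state: theta of the time-averaged rates.

    The time-averaged synchrony rates are shrunk toward the uniform model's
    expectations (eta_I = 2^-|I|) to pull them into the interior of the
    realizable set (zero joint counts are common at higher orders).
    Falls back to theta = 0 if the transform still fails.
    """
    iset = rates.index_set
    mean_rates = rates.rates.mean(axis=0)
    uniform = 0.5 ** iset.orders()
    eta0 = (1.0 - shrink) * mean_rates + shrink * uniform
    try:
        return eta_to_theta(ExpectationParams(iset, eta0), tol=1e-8).theta
    except ConvergenceError:
        return np.zeros(iset.dim)


def fit_em(rates: SynchronyRates, n_trials: int, order: int,
           state_model: str = "random_walk",
           init_hyper: StateHyperParams | None = None,
           max_iter: int = 500, tol: float = 1e-4,
           filter_options: FilterOptions | None = None,
           mstep_options: MStepOptions | None = None,
           q_scale: float = 0.01) -> FitResult:
    """Fit a state-space log-linear model of a given interaction order by EM.

    Parameters
    ----------
    rates : SynchronyRates
        Synchrony rates of order >= ``order``; truncated internally.
    n_trials : int
        Number of trials R behind the rates.
    order : int
        Interaction order m of the log-linear observation model.
    state_model : {'static', 'random_walk', 'ar1'}
        static: A = I and Q = 0 fixed (a stationary maximum-entropy fit);
        random_walk: A = I fixed, Q optimized; ar1: A and Q optimized.
    init_hyper : StateHyperParams, optional
        Overrides the default initialization (A = I, Q = q_scale*I,
        Sigma = I, mu from the time-averaged rates).
    max_iter, tol :
        EM stops when the increment of the approximate log marginal
        likelihood falls below ``tol`` (or after ``max_iter`` iterations).

    Returns
    -------
    FitResult
        Deterministic given the inputs.
    """
    if state_model not in STATE_MODELS:
        raise ValueError(f"state_model must be one of {STATE_MODELS}")
    if order > rates.index_set.max_order:
        raise ValueError("rates were computed at a lower order than requested")
    sub = rates.truncate(order)
    d = sub.index_set.dim
    if init_hyper is None:
        mu0 = initial_mean_from_rates(sub)
        hyper = StateHyperParams.default(d, state_model, initial_mean=mu0,
                                         q_scale=q_scale)
    else:
        hyper = init_hyper
    history = []
    trajectory = None
    converged = False
    n_done = 0
    for it in range(max_iter):
        try:
            trajectory = run_estep(sub, n_trials, hyper, filter_options)
        except Exception as exc:
            raise RuntimeError(f"E-step failed at EM iteration {it + 1}: {exc}") from exc
        history.append(trajectory.approx_log_marginal)
        n_done = it + 1
        if it > 0 and abs(history[-1] - history[-2]) < tol:
            converged = True
            break
        if it < max_iter - 1:
            hyper = mstep(trajectory, hyper, mstep_options)
    return FitResult(hyper, trajectory, history, n_done, converged,
                     order, n_trials, sub.rates.shape[0],
                     index_set=sub.index_set, state_model=state_model)
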