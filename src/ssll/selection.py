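"""Goodness-of-fit comparison of hierarchical state-space log-linear models.

Candidate models (interaction order m, state-transition family) are scored
by information criteria built on the Laplace-approximated log marginal
likelihood l(w):

    AIC  = -2 l(w) + 2 k_w
    BIC  = -2 l(w) + k_w log(n_obs)
    PDIO = -2 l(w) + 2 tr(J)

where k_w counts the free hyper-parameters of the state prior and J is the
Jacobian of the one-step EM operator at the converged hyper-parameters
(approximated by numerical differentiation, following Meng & Rubin's
supplemented-EM scheme).  The minimizing order is reported per criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .em import FitResult, MStepOptions, fit_em, mstep
from .spikedata import SynchronyRates
from .statespace import StateHyperParams, run_estep

logger = logging.getLogger(__name__)

__all__ = ["CriterionReport", "count_free_hyperparams", "aic", "bic", "pdio",
           "select_order", "em_map_jacobian"]


def count_free_hyperparams(d: int, state_model: str) -> int:
    """Free hyper-parameter count k_w of the state prior.

    ar1: d^2 (A) + d(d+1)/2 (Q) + d (mu); random_walk: d(d+1)/2 + d;
    static: d (mu only).  Sigma is never free.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if state_model == "ar1":
        return d * d + d * (d + 1) // 2 + d
    if state_model == "random_walk":
        return d * (d + 1) // 2 + d
    if state_model == "static":
        return d
    raise ValueError(f"unknown state_model {state_model!r}")


def aic(fit: FitResult) -> float:
    """Akaike information criterion for the latent-variable model."""
    k = count_free_hyperparams(fit.hyper.dim, fit.state_model)
    return -2.0 * fit.approx_log_marginal + 2.0 * k


def bic(fit: FitResult, n_obs: int | None = None) -> float:
    """Schwarz criterion; sample size defaults to R*T observations."""
    k = count_free_hyperparams(fit.hyper.dim, fit.state_model)
    if n_obs is None:
        n_obs = fit.n_trials * fit.n_bins
    return -2.0 * fit.approx_log_marginal + k * float(np.log(n_obs))


# ---------------------------------------------------------------------------
# PDIO: trace of the EM-map Jacobian
# ---------------------------------------------------------------------------

def _pack_hyper(hyper: StateHyperParams, state_model: str) -> np.ndarray:
    d = hyper.dim
    parts = []
    if state_model == "ar1":
        parts.append(hyper.transition.ravel())
    if state_model in ("ar1", "random_walk"):
        parts.append(hyper.innovation_cov[np.tril_indices(d)])
    parts.append(hyper.initial_mean)
    return np.concatenate(parts)


def _unpack_hyper(w: np.ndarray, template: StateHyperParams,
                  state_model: str) -> StateHyperParams:
    d = template.dim
    pos = 0
    if state_model == "ar1":
        A = w[pos:pos + d * d].reshape(d, d)
        pos += d * d
    else:
        A = np.eye(d)
    if state_model in ("ar1", "random_walk"):
        ntril = d * (d + 1) // 2
        Q = np.zeros((d, d))
        Q[np.tril_indices(d)] = w[pos:pos + ntril]
        Q = Q + np.tril(Q, -1).T
        pos += ntril
    else:
        Q = np.zeros((d, d))
    mu = w[pos:pos + d]
    return StateHyperParams(
        A, Q, mu, template.initial_cov.copy(),
        fix_transition_identity=template.fix_transition_identity,
        fix_innovation_zero=template.fix_innovation_zero,
    )


def em_map_jacobian(em_map, w0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Jacobian of a one-step EM operator at w0.

    ``em_map`` maps a flat hyper-parameter vector to the vector after one
    EM iteration.  Column j uses a relative perturbation of coordinate j.
    """
    w0 = np.asarray(w0, dtype=float)
    n = w0.size
    J = np.zeros((n, n))
    for j in range(n):
        h = rel_step * max(abs(w0[j]), 1e-3)
        wp = w0.copy()
        wp[j] += h
        wm = w0.copy()
        wm[j] -= h
        try:
            J[:, j] = (em_map(wp) - em_map(wm)) / (2.0 * h)
        except Exception as exc:
            raise RuntimeError(
                f"EM step failed while perturbing hyper-parameter {j}: {exc}"
            ) from exc
    return J


def pdio(fit: FitResult, rates: SynchronyRates, n_trials: int,
         rel_step: float = 1e-4) -> float:
    """Predictive divergence for indirect observation models.

    Penalizes the marginal likelihood by twice the trace of the EM-map
    Jacobian at the converged hyper-parameters.
    """
    sub = rates.truncate(fit.order)
    state_model = fit.state_model

    def em_map(w):
        hyper = _unpack_hyper(w, fit.hyper, state_model)
        traj = run_estep(sub, n_trials, hyper)
        new = mstep(traj, hyper)
        return _pack_hyper(new, state_model)

    w0 = _pack_hyper(fit.hyper, state_model)
    J = em_map_jacobian(em_map, w0, rel_step)
    return -2.0 * fit.approx_log_marginal + 2.0 * float(np.trace(J))


@dataclass
class CriterionReport:
    """Information-criterion table over candidate interaction orders."""

    table: pd.DataFrame            # one row per candidate order
    selected: dict                 # criterion name -> arg-min order
    fits: dict = field(default_factory=dict)   # order -> FitResult

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def select_order(rates: SynchronyRates, n_trials: int, orders,
                 criteria=("aic", "bic"), state_model: str = "random_walk",
                 compute_pdio: bool = False, **fit_kwargs) -> CriterionReport:
    """Fit each candidate order with identical settings and rank by criteria.

    Failed fits are recorded with a warning and excluded from the arg-min.
    """
    criteria = list(criteria)
    if compute_pdio and "pdio" not in criteria:
        criteria.append("pdio")
    rows = []
    fits = {}
    for m in orders:
        if m > rates.index_set.max_order:
            raise ValueError(f"order {m} exceeds the available rates order")
        row = {"order": m}
        try:
            fit = fit_em(rates, n_trials, m, state_model=state_model, **fit_kwargs)
        except Exception as exc:
            warnings.warn(f"fit of order {m} failed and is excluded: {exc}")
            rows.append(row)
            continue
        fits[m] = fit
        row["log_marginal"] = fit.approx_log_marginal
        row["k_w"] = count_free_hyperparams(fit.hyper.dim, state_model)
        if "aic" in criteria:
            row["aic"] = aic(fit)
        if "bic" in criteria:
            row["bic"] = bic(fit)
        if "pdio" in criteria:
            row["pdio"] = pdio(fit, rates, n_trials)
        rows.append(row)
    table = pd.DataFrame(rows)
    selected = {}
    for crit in criteria:
        if crit in table.columns and table[crit].notna().any():
            selected[crit] = int(table.loc[table[crit].idxmin(), "order"])
    return CriterionReport(table, selected, fits)
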