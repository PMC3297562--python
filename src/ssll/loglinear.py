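"""Exact log-linear (maximum-entropy) models of N-tuple binary spike patterns.

A population of N neurons observed in one time bin produces a binary pattern
``x = (x_1, ..., x_N)``.  The log-linear model writes the pattern probability
as an exponential family over products of subsets of the variables,

    log p(x) = sum_I theta_I * prod_{i in I} x_i  -  psi(theta),

where I runs over all nonempty neuron subsets up to a chosen interaction
order m.  The coefficients theta (natural parameters) quantify pure k-th
order interactions; their duals eta (expectation parameters) are the joint
spike probabilities E[prod_{i in I} X_i].  Everything here works by exact
enumeration of the 2^N patterns, which is the regime (N up to ~10-12 in
practice) where higher-order interaction analysis is feasible.

Conventions
-----------
* Pattern id: neuron i is bit i-1 (little-endian), so pattern
  ``x`` has id ``sum_i x_i 2^(i-1)``.
* Multi-indices are 1-based neuron subsets, ordered by interaction order
  ascending and lexicographically within an order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy.special import logsumexp

MAX_NEURONS = 20
_ENUMERATION_WARN = 12

__all__ = [
    "MultiIndexSet",
    "LogLinearParams",
    "ExpectationParams",
    "PatternDistribution",
    "ConvergenceError",
    "build_multi_indices",
    "feature_matrix",
    "log_partition",
    "pattern_distribution",
    "theta_to_eta",
    "eta_to_theta",
    "fisher_metric",
    "kl_divergence",
    "project_to_order",
    "solve_mixed_coordinates",
]


class ConvergenceError(RuntimeError):
    """Raised when an iterative coordinate transform fails to converge."""


@dataclass(frozen=True)
class MultiIndexSet:
    """Ordered collection of interaction multi-indices up to a given order.

    Attributes
    ----------
    n_neurons : int
        Population size N (1-based neuron ids).
    max_order : int
        Highest interaction order m included, 1 <= m <= N.
    indices : tuple of tuple of int
        All nonempty subsets of {1..N} of size <= m, sorted by size then
        lexicographically.
    """

    n_neurons: int
    max_order: int
    indices: tuple

    @property
    def dim(self) -> int:
        return len(self.indices)

    def position(self, index) -> int:
        """Vector position of a multi-index (e.g. ``(1, 3)``)."""
        return self.indices.index(tuple(sorted(index)))

    def order_slice(self, k: int) -> slice:
        """Slice covering all indices of order exactly ``k``."""
        start = sum(math.comb(self.n_neurons, j) for j in range(1, k))
        return slice(start, start + math.comb(self.n_neurons, k))

    def truncate(self, k: int) -> "MultiIndexSet":
        if not 1 <= k <= self.max_order:
            raise ValueError(f"cannot truncate order-{self.max_order} set to {k}")
        return build_multi_indices(self.n_neurons, k)

    def orders(self) -> np.ndarray:
        """Interaction order of each index, as an integer vector."""
        return np.array([len(ix) for ix in self.indices])

    def labels(self) -> list:
        return [",".join(map(str, ix)) for ix in self.indices]


@dataclass(frozen=True)
class LogLinearParams:
    """Natural (theta) coordinates of one log-linear distribution."""

    index_set: MultiIndexSet
    theta: np.ndarray

    def __post_init__(self):
        th = np.asarray(self.theta, dtype=float)
        if th.shape != (self.index_set.dim,):
            raise ValueError(
                f"theta has shape {th.shape}, expected ({self.index_set.dim},)"
            )
        if not np.all(np.isfinite(th)):
            raise ValueError("theta must be finite")
        object.__setattr__(self, "theta", th)


@dataclass(frozen=True)
class ExpectationParams:
    """Expectation (eta) coordinates: joint spike probabilities per subset."""

    index_set: MultiIndexSet
    eta: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.eta, dtype=float)
        if e.shape != (self.index_set.dim,):
            raise ValueError(
                f"eta has shape {e.shape}, expected ({self.index_set.dim},)"
            )
        object.__setattr__(self, "eta", e)


@dataclass(frozen=True)
class PatternDistribution:
    """Probability mass over the 2^N binary patterns (little-endian ids)."""

    n_neurons: int
    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (2**self.n_neurons,):
            raise ValueError("probs length must be 2^N")
        object.__setattr__(self, "probs", p)


@lru_cache(maxsize=128)
def build_multi_indices(n_neurons: int, max_order: int) -> MultiIndexSet:
    """Canonical ordered set of interaction indices for N neurons, order m.

    Raises
    ------
    ValueError
        If the order is outside 1..N or N exceeds the enumeration cap.
    """
    if not isinstance(n_neurons, (int, np.integer)) or not isinstance(
        max_order, (int, np.integer)
    ):
        raise ValueError("n_neurons and max_order must be integers")
    if n_neurons < 1 or n_neurons > MAX_NEURONS:
        raise ValueError(f"n_neurons must be in 1..{MAX_NEURONS}, got {n_neurons}")
    if not 1 <= max_order <= n_neurons:
        raise ValueError(f"max_order must be in 1..{n_neurons}, got {max_order}")
    if n_neurons > _ENUMERATION_WARN:
        warnings.warn(
            f"N={n_neurons} requires enumeration of 2^{n_neurons} patterns; "
            "expect slow transforms",
            RuntimeWarning,
            stacklevel=2,
        )
    idx = []
    for k in range(1, max_order + 1):
        idx.extend(combinations(range(1, n_neurons + 1), k))
    return MultiIndexSet(int(n_neurons), int(max_order), tuple(idx))


@lru_cache(maxsize=128)
def _feature_matrix_cached(n_neurons: int, max_order: int) -> np.ndarray:
    iset = build_multi_indices(n_neurons, max_order)
    n_pat = 2**n_neurons
    pats = np.arange(n_pat)[:, None]
    bits = (pats >> np.arange(n_neurons)) & 1  # (2^N, N), neuron i -> col i-1
    F = np.empty((n_pat, iset.dim))
    for j, index in enumerate(iset.indices):
        cols = [i - 1 for i in index]
        F[:, j] = bits[:, cols].prod(axis=1)
    F.setflags(write=False)
    return F


def feature_matrix(index_set: MultiIndexSet) -> np.ndarray:
    """Binary matrix F of shape (2^N, dim): F[x, I] = prod_{i in I} x_i."""
    return _feature_matrix_cached(index_set.n_neurons, index_set.max_order)


def log_partition(params: LogLinearParams) -> float:
    """Log normalizer psi(theta) = log sum_x exp(theta' f(x)), overflow-safe."""
    F = feature_matrix(params.index_set)
    return float(logsumexp(F @ params.theta))


def pattern_distribution(params: LogLinearParams) -> PatternDistribution:
    """Exact pattern probabilities p(x) = exp(theta' f(x) - psi)."""
    F = feature_matrix(params.index_set)
    s = F @ params.theta
    s -= s.max()
    p = np.exp(s)
    p /= p.sum()
    return PatternDistribution(params.index_set.n_neurons, p)


def theta_to_eta(params: LogLinearParams) -> ExpectationParams:
    """Forward Legendre map: eta_I = E[prod_{i in I} X_i] = grad psi(theta)."""
    F = feature_matrix(params.index_set)
    p = pattern_distribution(params).probs
    return ExpectationParams(params.index_set, F.T @ p)


def fisher_metric(params: LogLinearParams) -> np.ndarray:
    """Fisher information G = Cov[f(X)], i.e. G_IJ = eta_{I u J} - eta_I eta_J."""
    F = feature_matrix(params.index_set)
    p = pattern_distribution(params).probs
    eta = F.T @ p
    G = (F.T * p) @ F - np.outer(eta, eta)
    return 0.5 * (G + G.T)


def eta_to_theta(
    expect: ExpectationParams,
    tol: float = 1e-11,
    max_iter: int = 200,
) -> LogLinearParams:
    """Inverse Legendre map by damped Newton on the convex dual.

    Maximizes ``theta' eta - psi(theta)`` starting at theta = 0 with the
    Fisher metric as Hessian and step halving; converges when
    ``max|eta(theta) - eta| < tol``.  The tolerance sits well below the
    1e-9 eta accuracy the transforms guarantee, because an ill-conditioned
    Fisher metric (low joint-spike probabilities) amplifies the eta
    residual into a larger theta error.

    Raises
    ------
    ConvergenceError
        If eta is outside (or too close to the boundary of) the realizable
        set; the message names the residual and tolerance.
    """
    iset = expect.index_set
    target = np.asarray(expect.eta, dtype=float)
    if np.any(target <= 0.0) or np.any(target >= 1.0):
        raise ConvergenceError("eta entries must lie strictly in (0, 1)")
    F = feature_matrix(iset)
    theta = np.zeros(iset.dim)

    def dual(th):
        return th @ target - logsumexp(F @ th)

    obj = dual(theta)
    for _ in range(max_iter):
        s = F @ theta
        s -= s.max()
        p = np.exp(s)
        p /= p.sum()
        eta = F.T @ p
        resid = target - eta
        if np.max(np.abs(resid)) < tol:
            return LogLinearParams(iset, theta)
        G = (F.T * p) @ F - np.outer(eta, eta)
        G[np.diag_indices_from(G)] += 1e-13
        try:
            step = np.linalg.solve(G, resid)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate
            raise ConvergenceError(f"singular Fisher metric: {exc}") from exc
        alpha = 1.0
        for _ in range(60):
            cand = theta + alpha * step
            cand_obj = dual(cand)
            if cand_obj > obj or np.isclose(cand_obj, obj, rtol=0, atol=1e-15):
                theta, obj = cand, cand_obj
                break
            alpha *= 0.5
        else:  # no ascent possible: eta is on/outside the boundary
            break
    s = F @ theta
    s -= s.max()
    p = np.exp(s)
    p /= p.sum()
    resid = np.max(np.abs(target - F.T @ p))
    raise ConvergenceError(
        f"eta_to_theta did not reach |eta residual| < {tol:g} "
        f"(final residual {resid:.3g}); eta may be unrealizable"
    )


def kl_divergence(p: LogLinearParams, q: LogLinearParams) -> float:
    """Kullback-Leibler divergence D(p || q) in nats, by enumeration.

    Models may have different interaction orders but must share N; the
    lower-order model is implicitly embedded by zero-padding theta.
    """
    if p.index_set.n_neurons != q.index_set.n_neurons:
        raise ValueError("KL divergence requires models on the same N neurons")
    pp = pattern_distribution(p).probs
    qp = pattern_distribution(q).probs
    return float(np.sum(pp * (np.log(pp) - np.log(qp))))


def project_to_order(params: LogLinearParams, k: int, tol: float = 1e-9) -> LogLinearParams:
    """m-projection onto the order-k sub-manifold.

    The projected model preserves all eta up to order k and has zero theta
    above order k; computed as theta -> eta, truncate, eta -> theta.
    """
    if not 1 <= k <= params.index_set.max_order:
        raise ValueError(f"projection order {k} outside 1..{params.index_set.max_order}")
    if k == params.index_set.max_order:
        return params
    sub = params.index_set.truncate(k)
    eta = theta_to_eta(params).eta[: sub.dim]
    return eta_to_theta(ExpectationParams(sub, eta), tol=tol)


def solve_mixed_coordinates(
    index_set: MultiIndexSet,
    target_eta: np.ndarray,
    free: np.ndarray,
    theta_fixed: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> LogLinearParams:
    """Solve a mixed-coordinate specification of a log-linear model.

    Finds theta such that ``eta_I(theta) = target_eta[I]`` on the ``free``
    coordinates while ``theta[~free] = theta_fixed[~free]``.  This is the
    standard mixed (eta-low / theta-high) parameterization used e.g. to
    build a model with prescribed marginal rates and a prescribed top-order
    interaction.  Solved by Newton iterations on the free block with the
    corresponding Fisher sub-metric.
    """
    free = np.asarray(free, dtype=bool)
    target = np.asarray(target_eta, dtype=float)
    F = feature_matrix(index_set)
    theta = np.array(theta_fixed, dtype=float)
    theta[free] = 0.0
    for _ in range(max_iter):
        s = F @ theta
        s -= s.max()
        p = np.exp(s)
        p /= p.sum()
        eta = F.T @ p
        resid = target[free] - eta[free]
        if np.max(np.abs(resid)) < tol:
            return LogLinearParams(index_set, theta)
        G = (F.T * p) @ F - np.outer(eta, eta)
        Gff = G[np.ix_(free, free)]
        Gff[np.diag_indices_from(Gff)] += 1e-13
        step = np.linalg.solve(Gff, resid)
        # damp long steps; the restricted problem is still convex in theta_free
        nrm = np.max(np.abs(step))
        if nrm > 4.0:
            step *= 4.0 / nrm
        theta[free] += step
    raise ConvergenceError(
        f"mixed-coordinate solve did not converge below {tol:g} "
        f"(residual {np.max(np.abs(resid)):.3g})"
    )
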