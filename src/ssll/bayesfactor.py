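"""Bayes factors for sign-constrained interaction hypotheses and the
surrogate significance test.

For two hypothesis regions Theta_1, Theta_2 of natural-parameter space
(e.g. "the triple-wise interaction is positive" vs its complement), the
bin-by-bin Bayes factor compares how the observation at bin t updates the
odds between the regions:

    BF_t = [ P_filt(Theta_1) / P_filt(Theta_2) ]
           / [ P_pred(Theta_1) / P_pred(Theta_2) ],

with P_filt and P_pred the Gaussian filter and one-step prediction
probabilities of the regions (unconstrained coordinates marginalized out
analytically).  Summing log2 BF_t over a behavioral epoch gives the weight
of evidence in bits.  Because verbal calibrations of Bayes-factor size are
subjective, significance is assessed against surrogate data resampled from
a fitted lower-order (null) model that preserves the time-varying rates
and lower-order correlations but destroys the tested interaction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import multivariate_normal

from .em import FitResult, fit_em
from .loglinear import MultiIndexSet, build_multi_indices
from .spikedata import BinnedSpikeTensor, SynchronyRates, synchrony_rates
from .statespace import FilterOptions, GaussianBelief

logger = logging.getLogger(__name__)

__all__ = [
    "HypothesisRegion",
    "BayesFactorSeries",
    "SurrogateTestResult",
    "region_probability",
    "bin_bf",
    "bf_series",
    "interval_weight_of_evidence",
    "make_triplewise_test",
    "make_pairwise_clique_test",
    "surrogate_test",
]

MAX_CONSTRAINED_DIMS = 6
_PROB_FLOOR = 1e-300
LOG2E = 1.0 / math.log(2.0)


@dataclass(frozen=True)
class HypothesisRegion:
    """Sign-constraint region of theta-space.

    ``constraints`` is a list of (multi-index, sign) pairs with sign in
    {'positive', 'nonpositive'}; unconstrained parameters are implicitly
    unrestricted and integrated out.  ``mode='conjunction'`` requires all
    constraints to hold; ``mode='complement'`` is the negation of that
    conjunction.
    """

    index_set: MultiIndexSet
    constraints: tuple
    mode: str = "conjunction"

    def __post_init__(self):
        if self.mode not in ("conjunction", "complement"):
            raise ValueError("mode must be 'conjunction' or 'complement'")
        if not self.constraints:
            raise ValueError("at least one constraint is required")
        norm = []
        for index, sign in self.constraints:
            if sign not in ("positive", "nonpositive"):
                raise ValueError(f"unknown sign {sign!r}")
            tup = tuple(sorted(index))
            if tup not in self.index_set.indices:
                raise ValueError(f"constrained index {tup} not in the model")
            norm.append((tup, sign))
        object.__setattr__(self, "constraints", tuple(norm))

    def positions(self):
        return [self.index_set.position(ix) for ix, _ in self.constraints]

    def signs(self):
        """+1 for 'positive' (theta > 0), -1 for 'nonpositive' (theta <= 0)."""
        return np.array([1.0 if s == "positive" else -1.0
                         for _, s in self.constraints])


def _orthant_probability(mean: np.ndarray, cov: np.ndarray) -> float:
    """P(X > 0 componentwise) for X ~ N(mean, cov).

    One dimension uses the closed form; higher dimensions use the Genz
    algorithm behind scipy's multivariate normal CDF (deterministic given
    identical inputs).
    """
    k = mean.size
    if k == 1:
        return 0.5 * math.erfc(-mean[0] / math.sqrt(2.0 * cov[0, 0]))
    if k > MAX_CONSTRAINED_DIMS:
        raise ValueError(
            f"orthant probabilities support at most {MAX_CONSTRAINED_DIMS} "
            f"constrained dimensions, got {k}"
        )
    # P(X > 0) = P(-X < 0) = CDF of N(-mean, cov) at the origin
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = multivariate_normal(mean=-mean, cov=cov, allow_singular=False,
                                  seed=0).cdf(np.zeros(k))
    return float(val)


def region_probability(belief: GaussianBelief, region: HypothesisRegion) -> float:
    """Probability mass the Gaussian belief assigns to the region.

    Unconstrained coordinates are marginalized analytically (Gaussian
    marginals); the conjunction reduces to a multivariate-normal orthant
    probability after sign-flipping the 'nonpositive' coordinates.  The
    result is clipped away from exactly 0/1.
    """
    pos = region.positions()
    s = region.signs()
    mean = belief.mean[pos] * s
    cov = (belief.cov[np.ix_(pos, pos)]) * np.outer(s, s)
    if np.min(np.diag(cov)) <= 0:
        raise ValueError("degenerate marginal covariance in region probability")
    p = _orthant_probability(mean, cov)
    if region.mode == "complement":
        p = 1.0 - p
    if p <= _PROB_FLOOR or p >= 1.0 - 1e-16:
        logger.warning("region probability clipped at numerical bounds")
        p = min(max(p, _PROB_FLOOR), 1.0 - 1e-16)
    return p


def bin_bf(filt: GaussianBelief, pred: GaussianBelief,
           region1: HypothesisRegion, region2: HypothesisRegion) -> float:
    """Bin-by-bin log2 Bayes factor (bits): filter odds over prediction odds."""
    lf1 = math.log(region_probability(filt, region1))
    lf2 = math.log(region_probability(filt, region2))
    lp1 = math.log(region_probability(pred, region1))
    lp2 = math.log(region_probability(pred, region2))
    return ((lf1 - lf2) - (lp1 - lp2)) * LOG2E


@dataclass
class BayesFactorSeries:
    """Per-bin log2 Bayes factors for one hypothesis pair."""

    values: np.ndarray
    region1: HypothesisRegion
    region2: HypothesisRegion
    description: str = ""

    @property
    def n_bins(self) -> int:
        return self.values.size

    def total(self) -> float:
        return float(self.values.sum())


def bf_series(fit: FitResult, region1: HypothesisRegion,
              region2: HypothesisRegion, description: str = "") -> BayesFactorSeries:
    """Bin-by-bin BF over a fitted trajectory's filter/prediction beliefs."""
    traj = fit.trajectory
    fp = {
        "filt_mean": np.array([b.mean for b in traj.filters]),
        "filt_cov": np.array([b.cov for b in traj.filters]),
        "pred_mean": np.array([b.mean for b in traj.predictions]),
        "pred_cov": np.array([b.cov for b in traj.predictions]),
    }
    vals = _bf_values_from_arrays(fp, region1, region2)
    return BayesFactorSeries(vals, region1, region2, description)


def interval_weight_of_evidence(series: BayesFactorSeries,
                                t_from: int, t_to: int) -> float:
    """Weight of evidence (bits) over bins [t_from, t_to), 0-based half-open.

    Additive over disjoint intervals by construction.
    """
    if not 0 <= t_from < t_to <= series.n_bins:
        raise ValueError(f"empty or invalid interval [{t_from}, {t_to})")
    return float(series.values[t_from:t_to].sum())


def make_triplewise_test(n_neurons: int):
    """Hypothesis pair for the top-order interaction of a full model.

    region1: the order-N interaction parameter is positive; region2: it is
    zero or negative.  Lower-order parameters are unconstrained.  Requires
    a full (m = N) model downstream.
    """
    if n_neurons < 3:
        raise ValueError("top-order test needs N >= 3")
    iset = build_multi_indices(n_neurons, n_neurons)
    top = tuple(range(1, n_neurons + 1))
    r1 = HypothesisRegion(iset, ((top, "positive"),))
    r2 = HypothesisRegion(iset, ((top, "nonpositive"),))
    return r1, r2


def make_pairwise_clique_test(subset, n_neurons: int | None = None):
    """Hypothesis pair for a clique of simultaneously positive pairwise
    interactions among ``subset`` (1-based neuron ids).

    region1: theta_ij > 0 for every pair in the subset; region2: its
    complement (at least one pair not positive).  Use with a pairwise
    (m = 2) model fit.
    """
    subset = tuple(sorted(subset))
    if len(subset) < 2:
        raise ValueError("a clique needs at least two neurons")
    if n_neurons is None:
        n_neurons = max(subset)
    iset = build_multi_indices(n_neurons, 2)
    from itertools import combinations

    pairs = tuple((p, "positive") for p in combinations(subset, 2))
    r1 = HypothesisRegion(iset, pairs, mode="conjunction")
    r2 = HypothesisRegion(iset, pairs, mode="complement")
    return r1, r2


@dataclass
class SurrogateTestResult:
    """Two-sided surrogate test of an interval weight of evidence."""

    observed_log2_bf: float
    null_distribution: np.ndarray
    level: float
    ci_lower: float
    ci_upper: float
    decision: str                 # support_region1 | support_region2 | not_rejected
    n_surrogates: int
    seed: int
    description: str = ""


def _is_sign_pair(region1, region2):
    """True when the regions are {theta_j > 0} and {theta_j <= 0}."""
    return (len(region1.constraints) == 1 and len(region2.constraints) == 1
            and region1.mode == "conjunction" and region2.mode == "conjunction"
            and region1.constraints[0][0] == region2.constraints[0][0]
            and region1.constraints[0][1] == "positive"
            and region2.constraints[0][1] == "nonpositive")


def _bf_values_from_arrays(fp: dict, region1, region2) -> np.ndarray:
    """Per-bin log2 BF from a ``filter_pass`` result (vectorized 1-D case)."""
    if _is_sign_pair(region1, region2):
        from scipy.special import log_ndtr

        j = region1.positions()[0]
        zf = fp["filt_mean"][:, j] / np.sqrt(fp["filt_cov"][:, j, j])
        zp = fp["pred_mean"][:, j] / np.sqrt(fp["pred_cov"][:, j, j])
        return ((log_ndtr(zf) - log_ndtr(-zf))
                - (log_ndtr(zp) - log_ndtr(-zp))) * LOG2E
    T = fp["filt_mean"].shape[0]
    return np.array([
        bin_bf(GaussianBelief(fp["filt_mean"][t], fp["filt_cov"][t]),
               GaussianBelief(fp["pred_mean"][t], fp["pred_cov"][t]),
               region1, region2)
        for t in range(T)
    ])


def _fit_and_bf(tensor: BinnedSpikeTensor, order: int, region1, region2,
                hyper=None, state_model="random_walk", em_max_iter=20,
                em_tol=1e-3, filter_options=None, q_scale=0.01):
    rates = synchrony_rates(tensor, order)
    if hyper is not None:
        from .statespace import LogLinearObservations, filter_pass

        obs = LogLinearObservations(rates, tensor.n_trials)
        fp = filter_pass(obs, hyper, filter_options)
        return float(_bf_values_from_arrays(fp, region1, region2).sum()), None
    fit = fit_em(rates, tensor.n_trials, order, state_model=state_model,
                 max_iter=em_max_iter, tol=em_tol,
                 filter_options=filter_options, q_scale=q_scale)
    series = bf_series(fit, region1, region2)
    return series.total(), fit


def surrogate_test(tensor: BinnedSpikeTensor, interval, tested_order: int,
                   n_surrogates: int = 1000, level: float = 0.05,
                   seed: int = 0, hypothesis: str = "top_order",
                   clique_subset=None, refit_hyper: bool = True,
                   em_max_iter: int = 20, em_tol: float = 1e-3,
                   null_em_max_iter: int = 50,
                   filter_options: FilterOptions | None = None,
                   q_scale: float = 0.01) -> SurrogateTestResult:
    """Surrogate significance test for an order-k spike interaction.

    Procedure: (1) fit an order-(k-1) null model to the data in the tested
    interval (state model with A = I); (2) resample ``n_surrogates``
    datasets of R trials from the fitted null trajectory, preserving
    time-varying rates and lower-order correlations; (3) compute the
    order-k interval weight of evidence on the original data and on every
    surrogate; (4) two-sided decision at the empirical (level/2,
    1 - level/2) quantiles of the surrogate distribution.

    ``hypothesis='top_order'`` tests the order-k interaction of the first k
    neurons (k = N for the triple-wise test of a 3-neuron model);
    ``hypothesis='pairwise_clique'`` tests simultaneously positive pairwise
    interactions within ``clique_subset`` with k = 2.

    ``refit_hyper`` controls whether the innovation covariance is
    re-optimized by EM on every surrogate (default) or frozen at the value
    fitted to the original data (much faster for large surrogate counts).
    """
    if tested_order < 2:
        raise ValueError("tested_order must be >= 2")
    t_from, t_to = interval
    sub = tensor.window(t_from, t_to)
    N = sub.n_neurons
    if hypothesis == "top_order":
        if tested_order != N:
            raise ValueError("top-order test requires tested_order == N")
        region1, region2 = make_triplewise_test(N)
        desc = f"positive order-{N} interaction vs nonpositive"
    elif hypothesis == "pairwise_clique":
        if tested_order != 2:
            raise ValueError("clique test uses the pairwise model (order 2)")
        if clique_subset is None:
            clique_subset = tuple(range(1, N + 1))
        region1, region2 = make_pairwise_clique_test(clique_subset, N)
        desc = f"positive pairwise clique {tuple(clique_subset)} vs complement"
    else:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")

    ss = np.random.SeedSequence(seed)
    null_seed, surr_seed = ss.spawn(2)

    # null model: order k-1, A = I (recommended for sub-interval testing)
    null_rates = synchrony_rates(sub, tested_order - 1)
    null_fit = fit_em(null_rates, sub.n_trials, tested_order - 1,
                      state_model="random_walk", max_iter=null_em_max_iter,
                      tol=em_tol, filter_options=filter_options,
                      q_scale=q_scale)

    observed, obs_fit = _fit_and_bf(sub, tested_order, region1, region2,
                                    state_model="random_walk",
                                    em_max_iter=em_max_iter, em_tol=em_tol,
                                    filter_options=filter_options,
                                    q_scale=q_scale)
    frozen_hyper = None if refit_hyper else obs_fit.hyper

    from .simulate import sample_patterns

    null_theta = null_fit.trajectory.smoothed_means()
    child_seeds = surr_seed.spawn(n_surrogates)
    null_values = []
    failures = 0
    for i in range(n_surrogates):
        surr = sample_patterns(null_fit.index_set, null_theta, sub.n_trials,
                               rng=np.random.default_rng(child_seeds[i]),
                               bin_width=sub.bin_width)
        try:
            val, _ = _fit_and_bf(surr, tested_order, region1, region2,
                                 hyper=frozen_hyper,
                                 state_model="random_walk",
                                 em_max_iter=em_max_iter, em_tol=em_tol,
                                 filter_options=filter_options,
                                 q_scale=q_scale)
            null_values.append(val)
        except Exception as exc:
            failures += 1
            warnings.warn(f"surrogate {i} dropped: {exc}")
    if failures > 0.05 * n_surrogates:
        raise RuntimeError(
            f"{failures}/{n_surrogates} surrogate fits failed (> 5%)"
        )
    null_values = np.asarray(null_values)
    lo = float(np.quantile(null_values, level / 2.0))
    hi = float(np.quantile(null_values, 1.0 - level / 2.0))
    if observed > hi:
        decision = "support_region1"
    elif observed < lo:
        decision = "support_region2"
    else:
        decision = "not_rejected"
    return SurrogateTestResult(observed, null_values, level, lo, hi,
                               decision, n_surrogates, seed, desc)
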