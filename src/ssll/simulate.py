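"""Generation of parallel spike sequences from time-dependent log-linear
models, canonical simulation scenarios, and oracle risk measures.

Every scenario is a fully parameterized trajectory of natural parameters
theta_t; binary patterns are drawn independently across trials and bins
from the exact per-bin pattern distribution, which is the sampling
assumption behind the state-space likelihood.  The named scenarios are
documented parametric stand-ins for classic simulation designs (constant
rates with a transient correlation bump, independent rate-modulated
sequences, a pairwise-coupled 8-neuron network, a 3-neuron population with
time-varying pairwise and triple-wise interactions, and a three-period
stationary design whose final period carries a pure triple-wise
interaction that vanishes under pairwise projection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loglinear import (LogLinearParams, MultiIndexSet, build_multi_indices,
                        feature_matrix, kl_divergence, project_to_order,
                        solve_mixed_coordinates, theta_to_eta)
from .spikedata import BinnedSpikeTensor

__all__ = [
    "ScenarioSpec",
    "SCENARIO_NAMES",
    "sample_patterns",
    "build_scenario",
    "sample_surrogates",
    "oracle_risk",
]

SCENARIO_NAMES = (
    "pair_dynamic",
    "independent_rate_mod",
    "eight_neuron_pairwise",
    "triple_dynamic",
    "three_period_stationary",
)


@dataclass
class ScenarioSpec:
    """A fully specified simulation scenario: theta trajectory plus sizes."""

    name: str
    index_set: MultiIndexSet
    theta: np.ndarray            # (T, dim)
    n_trials: int
    bin_width: float = 0.004     # seconds; rate reporting uses eta / bin_width
    seed: int = 0

    @property
    def n_bins(self) -> int:
        return self.theta.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.index_set.n_neurons

    def eta_trajectory(self) -> np.ndarray:
        """Per-bin expectation parameters implied by the theta trajectory."""
        F = feature_matrix(self.index_set)
        s = self.theta @ F.T
        s -= s.max(axis=1, keepdims=True)
        p = np.exp(s)
        p /= p.sum(axis=1, keepdims=True)
        return p @ F

    def truth_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.theta, columns=self.index_set.labels())
        df.insert(0, "bin", np.arange(self.n_bins))
        return df

    def sample(self, rng=None) -> BinnedSpikeTensor:
        return sample_patterns(self.index_set, self.theta, self.n_trials,
                               seed=self.seed if rng is None else None,
                               rng=rng, bin_width=self.bin_width)


def sample_patterns(index_set: MultiIndexSet, theta_trajectory: np.ndarray,
                    n_trials: int, seed: int | None = None, rng=None,
                    bin_width: float = 0.004) -> BinnedSpikeTensor:
    """Draw R x T binary patterns from per-bin log-linear distributions.

    Patterns are independent across trials and bins; each bin-t pattern is
    drawn from the exact 2^N-point distribution induced by theta_t.
    Reproducible given the seed (or a supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    theta = np.atleast_2d(np.asarray(theta_trajectory, dtype=float))
    T, d = theta.shape
    if d != index_set.dim:
        raise ValueError("theta trajectory width must equal index_set.dim")
    N = index_set.n_neurons
    F = feature_matrix(index_set)
    s = theta @ F.T                     # (T, 2^N)
    s -= s.max(axis=1, keepdims=True)
    p = np.exp(s)
    p /= p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    u = rng.random((T, n_trials))
    ids = np.empty((T, n_trials), dtype=np.int64)
    for t in range(T):
        ids[t] = np.searchsorted(cum[t], u[t], side="right")
    ids = np.minimum(ids, 2**N - 1).T   # (R, T)
    bits = ((ids[..., None] >> np.arange(N)) & 1).astype(np.uint8)
    return BinnedSpikeTensor(bits, bin_width)


# ---------------------------------------------------------------------------
# trajectory building blocks
# ---------------------------------------------------------------------------

def _logit(p):
    return math.log(p / (1.0 - p))


def _smooth_bump(T, center, width, height):
    t = np.arange(T)
    return height * np.exp(-0.5 * ((t - center) / width) ** 2)


def _smooth_steps(T, knots, widths=None):
    """Piecewise-constant levels smoothed by cosine ramps.

    ``knots`` is a list of (start_bin, level); level holds until the next
    start.  Transitions are smoothed over ``widths`` bins (default T//25).
    """
    w = max(2, T // 25) if widths is None else widths
    out = np.full(T, knots[0][1], dtype=float)
    for (s, lev) in knots[1:]:
        prev = out[max(s - 1, 0)]
        ramp = np.arange(T) - s
        mask = ramp >= 0
        out[mask] = lev
        # cosine ramp over [s - w/2, s + w/2)
        lo, hi = max(0, s - w // 2), min(T, s + w // 2)
        if hi > lo:
            x = np.linspace(0, math.pi, hi - lo)
            out[lo:hi] = prev + (lev - prev) * 0.5 * (1 - np.cos(x))
    return out


def build_scenario(name: str, **overrides) -> ScenarioSpec:
    """Construct one of the canonical simulation scenarios.

    Override any of n_trials, n_bins, seed, bin_width, and per-scenario
    magnitude parameters (see the source of each builder).
    """
    builders = {
        "pair_dynamic": _pair_dynamic,
        "independent_rate_mod": _independent_rate_mod,
        "eight_neuron_pairwise": _eight_neuron_pairwise,
        "triple_dynamic": _triple_dynamic,
        "three_period_stationary": _three_period_stationary,
    }
    if name not in builders:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    return builders[name](**overrides)


def _pair_dynamic(n_trials=100, n_bins=500, seed=0, bin_width=0.004,
                  rate1=0.15, rate2=0.08, coupling_height=1.5):
    """Two neurons, constant rates, transient pairwise coupling bump."""
    iset = build_multi_indices(2, 2)
    T = n_bins
    th = np.zeros((T, 3))
    th[:, 0] = _logit(rate1)
    th[:, 1] = _logit(rate2)
    th[:, 2] = (_smooth_bump(T, T * 0.35, T * 0.07, coupling_height)
                + _smooth_bump(T, T * 0.7, T * 0.05, coupling_height * 0.8))
    return ScenarioSpec("pair_dynamic", iset, th, n_trials, bin_width, seed)


def _independent_rate_mod(n_trials=100, n_bins=500, seed=0, bin_width=0.004,
                          base_rate=0.1, mod_depth=0.8):
    """Two independent neurons with sinusoidally varying rates."""
    iset = build_multi_indices(2, 2)
    T = n_bins
    t = np.arange(T)
    th = np.zeros((T, 3))
    th[:, 0] = _logit(base_rate) + mod_depth * np.sin(2 * math.pi * t / T)
    th[:, 1] = _logit(base_rate) + mod_depth * np.sin(2 * math.pi * t / T + 1.5)
    return ScenarioSpec("independent_rate_mod", iset, th, n_trials, bin_width, seed)


def _eight_neuron_pairwise(n_trials=200, n_bins=500, seed=0, bin_width=0.004,
                           base_rate=0.1, rate_mod=0.6, coupling_scale=0.6):
    """Eight neurons, time-varying rates and pairwise couplings, no
    higher-order terms (m = 2)."""
    iset = build_multi_indices(8, 2)
    T = n_bins
    t = np.arange(T)
    rng = np.random.default_rng(seed + 7919)   # fixed phase draw per seed
    th = np.zeros((T, iset.dim))
    for j in range(8):
        phase = rng.uniform(0, 2 * math.pi)
        th[:, j] = _logit(base_rate) + rate_mod * np.sin(2 * math.pi * t / T + phase)
    for j in range(8, iset.dim):
        phase = rng.uniform(0, 2 * math.pi)
        amp = coupling_scale * rng.uniform(0.2, 1.0)
        th[:, j] = amp * np.sin(2 * math.pi * t / T + phase)
    return ScenarioSpec("eight_neuron_pairwise", iset, th, n_trials, bin_width, seed)


def _triple_dynamic(n_trials=500, n_bins=500, seed=0, bin_width=0.004,
                    base_rate=0.12, pair_amp=0.6, triple_amp=1.2):
    """Three neurons with time-varying pairwise and triple-wise terms.

    The triple-wise trajectory is positive in bins [0.2T, 0.4T) and in the
    second half of [0.6T, T), negative elsewhere, mimicking an epoch
    structure in which a higher-order assembly switches on twice.
    """
    iset = build_multi_indices(3, 3)
    T = n_bins
    t = np.arange(T)
    th = np.zeros((T, 7))
    for j in range(3):
        th[:, j] = _logit(base_rate) + 0.3 * np.sin(2 * math.pi * t / T + j)
    for j in range(3, 6):
        th[:, j] = pair_amp * np.sin(2 * math.pi * t / T + 0.7 * j)
    th[:, 6] = (_smooth_steps(T, [(0, -0.6), (int(0.2 * T), triple_amp),
                                  (int(0.4 * T), -0.8)])
                + _smooth_bump(T, 0.85 * T, 0.08 * T, triple_amp + 0.8))
    return ScenarioSpec("triple_dynamic", iset, th, n_trials, bin_width, seed)


def _three_period_stationary(n_trials=100, n_bins=300, seed=0, bin_width=0.004,
                             rate=0.1, pair_theta=0.6, triple_theta=2.5):
    """Three stationary periods with matched single-neuron rates (0.1/bin).

    Period I: independent spiking.  Period II: simultaneously positive
    pairwise interactions, no triple-wise term.  Period III: positive
    triple-wise interaction with negative pairwise terms solved so that the
    pairwise joint rates stay at the chance level rate^2 — the pairwise
    projection of period III is therefore the independent model, while the
    triple synchrony rate exceeds its chance value rate^3.
    """
    iset = build_multi_indices(3, 3)
    T = n_bins
    per = T // 3
    th_i = np.zeros(7)
    th_i[:3] = _logit(rate)

    # period II: fix pairwise/triple theta, solve first-order theta for the rates
    free = np.array([True] * 3 + [False] * 4)
    target = np.zeros(7)
    target[:3] = rate
    fixed = np.zeros(7)
    fixed[3:6] = pair_theta
    th_ii = solve_mixed_coordinates(iset, target, free, fixed).theta

    # period III: fix triple theta, solve orders 1-2 for chance pairwise rates
    free = np.array([True] * 6 + [False])
    target = np.zeros(7)
    target[:3] = rate
    target[3:6] = rate * rate
    fixed = np.zeros(7)
    fixed[6] = triple_theta
    th_iii = solve_mixed_coordinates(iset, target, free, fixed).theta

    th = np.zeros((T, 7))
    th[:per] = th_i
    th[per:2 * per] = th_ii
    th[2 * per:] = th_iii
    return ScenarioSpec("three_period_stationary", iset, th, n_trials,
                        bin_width, seed)


def sample_surrogates(fit, n: int, n_trials: int | None = None,
                      seed: int = 0, bin_width: float = 0.004):
    """Yield ``n`` surrogate tensors drawn from a fit's smoothed MAP
    trajectory, each with its own sub-seed."""
    theta = fit.trajectory.smoothed_means()
    R = fit.n_trials if n_trials is None else n_trials
    for child in np.random.SeedSequence(seed).spawn(n):
        yield sample_patterns(fit.index_set, theta, R,
                              rng=np.random.default_rng(child),
                              bin_width=bin_width)


def oracle_risk(true_theta: np.ndarray, est_theta: np.ndarray,
                true_index_set: MultiIndexSet,
                est_index_set: MultiIndexSet | None = None):
    """Truth-aware risk of an estimated trajectory: (total KL, total SE).

    Per bin, the KL divergence D(p_true || p_est) is summed over bins;
    orders absent from the estimated model count as zero.  The squared
    error sums |theta_true - theta_est|^2 over bins with the same zero
    padding.  Requires matching bin counts and neuron numbers.
    """
    true_theta = np.atleast_2d(true_theta)
    est_theta = np.atleast_2d(est_theta)
    if est_index_set is None:
        est_index_set = true_index_set
    if true_theta.shape[0] != est_theta.shape[0]:
        raise ValueError("trajectories must cover the same number of bins")
    if est_index_set.n_neurons != true_index_set.n_neurons:
        raise ValueError("models must share the number of neurons")
    if est_index_set.max_order > true_index_set.max_order:
        raise ValueError("estimated order must not exceed the true order")
    d_true = true_index_set.dim
    padded = np.zeros((est_theta.shape[0], d_true))
    padded[:, : est_index_set.dim] = est_theta
    kl = 0.0
    for t in range(true_theta.shape[0]):
        kl += kl_divergence(LogLinearParams(true_index_set, true_theta[t]),
                            LogLinearParams(true_index_set, padded[t]))
    se = float(np.sum((true_theta - padded) ** 2))
    return kl, se
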