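"""Filter/smoother machinery checked against linear-Gaussian oracles.

The Kalman filter, RTS smoother and the dense joint-Gaussian posterior are
implemented independently here and must agree with the package's Laplace
recursion to near machine precision when the observation model is Gaussian
(the Laplace approximation is then exact).
"""

import math

import numpy as np
import pytest
from scipy.stats import norm

import ssll
from ssll import (FilterOptions, GaussianBelief, GaussianObservations,
                  LogLinearObservations, StateHyperParams, build_multi_indices,
                  filter_update, predict, run_estep, synchrony_rates)
from ssll.spikedata import BinnedSpikeTensor, SynchronyRates
from ssll.statespace import filter_pass
from ssll import _kernels


def random_spd(rng, d, scale=1.0):
    A = rng.normal(size=(d, d))
    return scale * (A @ A.T + d * np.eye(d)) / d


def kalman_rts_oracle(y, H, S, A, Q, mu, Sigma):
    """Textbook Kalman filter + RTS smoother + lag-one covariances."""
    T, k = y.shape
    d = mu.size
    pm = np.zeros((T, d)); pc = np.zeros((T, d, d))
    fm = np.zeros((T, d)); fc = np.zeros((T, d, d))
    loglik = 0.0
    m, P = mu, Sigma
    for t in range(T):
        if t > 0:
            m = A @ fm[t - 1]
            P = A @ fc[t - 1] @ A.T + Q
        pm[t], pc[t] = m, P
        Sf = H @ P @ H.T + S
        K = P @ H.T @ np.linalg.inv(Sf)
        innov = y[t] - H @ m
        fm[t] = m + K @ innov
        fc[t] = (np.eye(d) - K @ H) @ P
        sign, logdet = np.linalg.slogdet(Sf)
        loglik += -0.5 * (innov @ np.linalg.solve(Sf, innov)
                          + logdet + k * math.log(2 * math.pi))
    sm = fm.copy(); sc = fc.copy()
    gains = np.zeros((T, d, d))
    for t in range(T - 2, -1, -1):
        J = fc[t] @ A.T @ np.linalg.inv(pc[t + 1])
        gains[t] = J
        sm[t] = fm[t] + J @ (sm[t + 1] - pm[t + 1])
        sc[t] = fc[t] + J @ (sc[t + 1] - pc[t + 1]) @ J.T
    lag = np.zeros((T, d, d))
    for t in range(1, T):
        lag[t] = sc[t] @ gains[t - 1].T
    return dict(pm=pm, pc=pc, fm=fm, fc=fc, sm=sm, sc=sc, lag=lag,
                loglik=loglik)


class TestPredict:
    def test_identity_no_noise_keeps_belief(self, rng):
        b = GaussianBelief(rng.normal(size=3), random_spd(rng, 3))
        hyper = StateHyperParams(np.eye(3), np.zeros((3, 3)),
                                 np.zeros(3), np.eye(3))
        out = predict(b, hyper)
        assert np.allclose(out.mean, b.mean)
        assert np.allclose(out.cov, b.cov)

    def test_contraction_halves_mean(self, rng):
        b = GaussianBelief(np.full(2, 2.0), np.eye(2))
        hyper = StateHyperParams(0.5 * np.eye(2), np.eye(2),
                                 np.zeros(2), np.eye(2))
        out = predict(b, hyper)
        assert np.allclose(out.mean, 1.0)
        assert np.allclose(out.cov, 0.25 * np.eye(2) + np.eye(2))

    def test_matches_direct_formula(self, rng):
        d = 4
        A = rng.normal(size=(d, d))
        Q = random_spd(rng, d)
        b = GaussianBelief(rng.normal(size=d), random_spd(rng, d))
        hyper = StateHyperParams(A, Q, np.zeros(d), np.eye(d))
        out = predict(b, hyper)
        assert np.allclose(out.mean, A @ b.mean)
        assert np.allclose(out.cov, A @ b.cov @ A.T + Q)


class TestFilterUpdate:
    def test_flat_prior_returns_mle(self):
        iset = build_multi_indices(1, 1)
        rates = SynchronyRates(iset, np.array([[0.5]]))
        obs = LogLinearObservations(rates, 100)
        pred = GaussianBelief(np.zeros(1), 1e6 * np.eye(1))
        out = filter_update(pred, obs, 0)
        assert abs(out.mean[0]) < 1e-4  # logit(0.5) = 0

    def test_fixed_point_condition_holds(self, rng):
        # the mode satisfies theta = pred + W_pred R (y - eta(theta))
        iset = build_multi_indices(2, 2)
        X = (rng.random((50, 1, 2)) < 0.3).astype(np.uint8)
        rates = synchrony_rates(BinnedSpikeTensor(X, 0.001), 2)
        obs = LogLinearObservations(rates, 50)
        pred = GaussianBelief(rng.normal(size=3) * 0.3, random_spd(rng, 3, 0.5))
        out = filter_update(pred, obs, 0)
        lhs = out.mean
        rhs = pred.mean + pred.cov @ (50 * (rates.rates[0] - obs.eta(out.mean)))
        assert np.max(np.abs(lhs - rhs)) < 1e-8

    def test_large_sample_concentrates_on_truth(self):
        iset = build_multi_indices(2, 2)
        theta_star = np.array([-1.0, 0.5, 0.8])
        eta = ssll.theta_to_eta(ssll.LogLinearParams(iset, theta_star)).eta
        rates = SynchronyRates(iset, eta[None, :])
        obs = LogLinearObservations(rates, 10**4)
        pred = GaussianBelief(np.zeros(3), np.eye(3))
        out = filter_update(pred, obs, 0)
        assert np.max(np.abs(out.mean - theta_star)) < 0.05

    def test_fast_approximation_tracks_full_filter(self):
        # single Newton step from the prediction mean: cheaper, close to
        # the fully iterated mode when trials are plentiful
        from ssll.em import initial_mean_from_rates

        spec = ssll.build_scenario("pair_dynamic", n_trials=300, n_bins=60,
                                   seed=6)
        rates = synchrony_rates(spec.sample(), 2)
        mu = initial_mean_from_rates(rates)
        hyper = StateHyperParams.default(3, "random_walk", initial_mean=mu)
        obs = LogLinearObservations(rates, 300)
        full = filter_pass(obs, hyper)
        fast = filter_pass(obs, hyper, FilterOptions(fast_approx=True))
        # after a short burn-in the single-step mode stays near the
        # fully iterated one
        diff = np.abs(full["filt_mean"] - fast["filt_mean"])
        assert diff[10:].max() < 0.05

    def test_covariances_positive_definite_throughout(self, rng):
        spec = ssll.build_scenario("triple_dynamic", n_trials=50, n_bins=60,
                                   seed=2)
        rates = synchrony_rates(spec.sample(), 3)
        hyper = StateHyperParams.default(7, "random_walk")
        traj = run_estep(rates, 50, hyper)
        for t in range(traj.n_bins):
            for b in (traj.predictions[t], traj.filters[t], traj.smoothed[t]):
                assert np.max(np.abs(b.cov - b.cov.T)) < 1e-12
                assert np.min(np.linalg.eigvalsh(b.cov)) > 0


class TestGaussianOracleEquivalence:
    @pytest.mark.parametrize("d,T", [(1, 10), (2, 30), (3, 50)])
    def test_filter_smoother_lag_one_match_kalman_rts(self, d, T):
        rng = np.random.default_rng(17 + d)
        k = d
        H = np.eye(k) + 0.1 * rng.normal(size=(k, d))
        S = random_spd(rng, k, 0.5)
        A = 0.9 * np.eye(d) + 0.05 * rng.normal(size=(d, d))
        Q = random_spd(rng, d, 0.1)
        mu = rng.normal(size=d)
        Sigma = random_spd(rng, d)
        y = rng.normal(size=(T, k))
        obs = GaussianObservations(y, H, S)
        hyper = StateHyperParams(A, Q, mu, Sigma)
        traj = run_estep(obs, None, hyper)
        oracle = kalman_rts_oracle(y, H, S, A, Q, mu, Sigma)
        for t in range(T):
            assert np.max(np.abs(traj.filters[t].mean - oracle["fm"][t])) < 1e-10
            assert np.max(np.abs(traj.filters[t].cov - oracle["fc"][t])) < 1e-10
            assert np.max(np.abs(traj.smoothed[t].mean - oracle["sm"][t])) < 1e-10
            assert np.max(np.abs(traj.smoothed[t].cov - oracle["sc"][t])) < 1e-10
            if t > 0:
                assert np.max(np.abs(traj.lag_one_cov[t] - oracle["lag"][t])) < 1e-10

    def test_marginal_likelihood_equals_prediction_error_decomposition(self):
        rng = np.random.default_rng(5)
        d = 2
        T = 40
        A = 0.8 * np.eye(d)
        Q = 0.3 * np.eye(d)
        H = np.eye(d)
        S = 0.5 * np.eye(d)
        mu = np.zeros(d)
        Sigma = np.eye(d)
        y = rng.normal(size=(T, d))
        traj = run_estep(GaussianObservations(y, H, S), None,
                         StateHyperParams(A, Q, mu, Sigma))
        oracle = kalman_rts_oracle(y, H, S, A, Q, mu, Sigma)
        assert traj.approx_log_marginal == pytest.approx(oracle["loglik"],
                                                         abs=1e-8)

    def test_smoothing_reduces_variance_in_oracle_case(self):
        rng = np.random.default_rng(9)
        d, T = 2, 25
        y = rng.normal(size=(T, d))
        obs = GaussianObservations(y, np.eye(d), np.eye(d))
        hyper = StateHyperParams(np.eye(d), 0.2 * np.eye(d),
                                 np.zeros(d), np.eye(d))
        traj = run_estep(obs, None, hyper)
        for t in range(T - 1):
            assert np.all(np.diag(traj.smoothed[t].cov)
                          <= np.diag(traj.filters[t].cov) + 1e-12)


class TestDenseJointOracle:
    def test_lag_one_matches_full_joint_gaussian(self):
        """Build the full Td-dimensional posterior precision and compare."""
        rng = np.random.default_rng(3)
        d, T = 2, 8
        A = 0.7 * np.eye(d) + 0.1 * rng.normal(size=(d, d))
        Q = random_spd(rng, d, 0.3)
        H = np.eye(d)
        S = random_spd(rng, d, 0.4)
        mu = rng.normal(size=d)
        Sigma = random_spd(rng, d)
        y = rng.normal(size=(T, d))
        Qi = np.linalg.inv(Q)
        Si = np.linalg.inv(S)
        Sgi = np.linalg.inv(Sigma)
        P = np.zeros((T * d, T * d))
        b = np.zeros(T * d)
        P[:d, :d] += Sgi
        b[:d] += Sgi @ mu
        for t in range(T):
            sl = slice(t * d, (t + 1) * d)
            P[sl, sl] += H.T @ Si @ H
            b[t * d:(t + 1) * d] += H.T @ Si @ y[t]
        for t in range(1, T):
            s0 = slice((t - 1) * d, t * d)
            s1 = slice(t * d, (t + 1) * d)
            P[s1, s1] += Qi
            P[s0, s0] += A.T @ Qi @ A
            P[np.ix_(range(s1.start, s1.stop), range(s0.start, s0.stop))] -= Qi @ A
            P[np.ix_(range(s0.start, s0.stop), range(s1.start, s1.stop))] -= A.T @ Qi
        cov = np.linalg.inv(P)
        mean = cov @ b
        traj = run_estep(GaussianObservations(y, H, S), None,
                         StateHyperParams(A, Q, mu, Sigma))
        for t in range(T):
            sl = slice(t * d, (t + 1) * d)
            assert np.max(np.abs(traj.smoothed[t].mean - mean[sl])) < 1e-9
            assert np.max(np.abs(traj.smoothed[t].cov - cov[sl, sl])) < 1e-9
            if t > 0:
                prev = slice((t - 1) * d, t * d)
                joint = cov[sl, prev]
                assert np.max(np.abs(traj.lag_one_cov[t] - joint)) < 1e-9

    def test_weak_coupling_decouples_lag_one(self):
        rng = np.random.default_rng(4)
        d, T = 2, 10
        y = rng.normal(size=(T, d))
        obs = GaussianObservations(y, np.eye(d), 0.5 * np.eye(d))
        hyper = StateHyperParams(np.eye(d), 1e6 * np.eye(d),
                                 np.zeros(d), np.eye(d))
        traj = run_estep(obs, None, hyper)
        for t in range(1, T):
            assert np.max(np.abs(traj.lag_one_cov[t])) < 1e-4


class TestMarginalLikelihood:
    def test_laplace_close_to_quadrature_on_tiny_model(self):
        """d=1, T=2 Bernoulli model vs nested numerical integration."""
        iset = build_multi_indices(1, 1)
        R = 10
        y = np.array([[0.4], [0.6]])
        rates = SynchronyRates(iset, y)
        a, q, m0, s0 = 1.0, 0.3, 0.0, 1.0
        hyper = StateHyperParams([[a]], [[q]], [m0], [[s0]])
        traj = run_estep(rates, R, hyper)

        def loglik(t, th):
            return R * (th * y[t, 0] - math.log(1 + math.exp(th)))

        grid = np.linspace(-6, 6, 2001)
        dx = grid[1] - grid[0]
        prior1 = norm.pdf(grid, m0, math.sqrt(s0))
        l1 = np.exp([loglik(0, th) for th in grid])
        # p(th2 | th1) integrated over th1 then times likelihood at t=2
        post_unnorm = prior1 * l1
        evidence1 = post_unnorm.sum() * dx
        mix = np.zeros_like(grid)
        for w, th1 in zip(post_unnorm / evidence1, grid):
            mix += w * norm.pdf(grid, a * th1, math.sqrt(q)) * dx
        l2 = np.exp([loglik(1, th) for th in grid])
        evidence2 = (mix * l2).sum() * dx
        exact = math.log(evidence1) + math.log(evidence2)
        assert traj.approx_log_marginal == pytest.approx(exact, abs=0.05)

    def test_kernel_and_reference_paths_agree(self, rng):
        spec = ssll.build_scenario("triple_dynamic", n_trials=40, n_bins=40,
                                   seed=8)
        rates = synchrony_rates(spec.sample(), 3)
        obs = LogLinearObservations(rates, 40)
        hyper = StateHyperParams.default(7, "random_walk")
        fp1 = filter_pass(obs, hyper)
        saved = _kernels.HAVE_NUMBA
        _kernels.HAVE_NUMBA = False
        try:
            fp2 = filter_pass(obs, hyper)
        finally:
            _kernels.HAVE_NUMBA = saved
        assert fp1["log_marginal"] == pytest.approx(fp2["log_marginal"],
                                                    abs=1e-8)
        assert np.max(np.abs(fp1["filt_mean"] - fp2["filt_mean"])) < 1e-10
        assert np.max(np.abs(fp1["filt_cov"] - fp2["filt_cov"])) < 1e-10
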