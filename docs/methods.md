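# Methods

## Model

`ssll` analyzes trial-aligned parallel spike trains of N neurons binned at
width Δ into binary patterns.  The per-bin pattern distribution is the
log-linear exponential family over all nonempty neuron subsets up to a
chosen interaction order m,

    log p(x | θ_t) = θ_t' f(x) − ψ(θ_t),    f_I(x) = Π_{i∈I} x_i,

with d = Σ_{k≤m} C(N,k) natural parameters per bin.  All transforms
(ψ, θ→η, Fisher metric, KL, m-projection) are computed by exact enumeration
of the 2^N patterns; the package enforces N ≤ 20 and warns above N = 12,
since enumeration is the practical regime for higher-order analysis.

The dual (expectation) coordinates η_I = E[Π_{i∈I} X_i] are the joint
spike probabilities.  θ and η are linked by the Legendre transform
(η = ∇ψ, G = ∇²ψ = Cov f(X)); the m-projection onto a lower-order manifold
preserves η up to that order and zeroes the higher-order θ.  A model's
"pure" order-k interaction is whatever its η cannot inherit from the
projection to order k−1 — e.g. a positive θ_123 with pairwise η at the
chance level of the rates produces excess spike triplets that no pairwise
model reproduces.

Dynamics: the natural-parameter vector follows a first-order linear-
Gaussian state equation θ_t = A θ_{t−1} + ξ_t, ξ_t ~ N(0, Q),
θ_1 ~ N(μ, Σ), observed through R independent trials per bin.  The per-bin
log-likelihood given the observed synchrony rates y_t (the sufficient
statistic) is R (θ' y_t − ψ(θ)).  Key assumptions: no spike-history
effects within trials (patterns conditionally independent across bins),
and identical statistics across trials (across-trial stationarity).  Both
are violated to some degree in real recordings — rate drift across trials
in particular can masquerade as higher-order correlation — and the
simulator deliberately generates data that satisfy them (see below).

## Estimation

E-step — recursive Gaussian approximation.  One-step prediction follows
Chapman–Kolmogorov (mean Aθ, covariance AWA' + Q).  The filter posterior
is log-concave, so its mode is found by Newton iterations (learning
coefficient α, default 1, with backtracking halving; convergence when all
increments < 1e−10, max 100 iterations — typically 3–8 suffice) and its
covariance is the inverse Hessian (R·G(mode) + W_pred^−1)^−1.  A
fixed-interval smoother (RTS form, gain A_t = W_t|t A' W_t+1|t^−1) runs
backwards; lag-one covariances use W_t|T A_{t−1}', validated against a
dense joint-Gaussian oracle.  Covariance inverses go through Cholesky with
1e−10 jitter on failure; covariances are explicitly symmetrized.  When the
observation model is Gaussian the whole recursion reduces exactly to
Kalman/RTS, which the test-suite exploits as an independent oracle at
1e−10.

The approximate log marginal likelihood sums per-bin Laplace evaluations
of the one-step predictive integral at the filter mode; on a d=1, T=2
model it is within 0.05 of brute-force quadrature (tested).

M-step.  Closed-form maximizers of the expected complete-data
log-likelihood using smoothed second moments: A from the lag-one
regression, Q from the innovation moments normalized by the number of
transitions (T−1, the exact maximizer), μ from the smoothed initial state.
Σ is never updated (held fixed at I); the stationary-prior alternative is
not used because a fitted A need not be stationary.  Q's spectrum is
floored at 0, and a diagonal-Q option exists for large d.

State models: `static` (A=I, Q=0 — a stationary maximum-entropy fit),
`random_walk` (A=I, Q optimized), `ar1` (A and Q optimized).
Initialization: A=I, Q=0.01·I, Σ=I, μ from the time-averaged synchrony
rates shrunk 5% toward the uniform model's expectations (keeps zero counts
inside the realizable set), θ=0 fallback.  EM stops when the marginal-
likelihood increment falls below 1e−4 (default) or at max_iter.  Because
of the Laplace approximation EM ascent is only approximate; the tests
allow a 0.1 slack per step and in practice the history is monotone.

Performance: the per-bin Newton filter is implemented twice — a reference
numpy recursion and a numba kernel (`ssll/_kernels.py`) used automatically
for log-linear observations.  Both agree to ~1e−15 (tested).  The kernel
makes the surrogate-test studies below tractable on one CPU (~20×).

## Model selection

AIC = −2l + 2k_w, BIC = −2l + k_w log(R·T), PDIO = −2l + 2 tr(J), where l
is the approximate log marginal likelihood, k_w counts free
hyper-parameters (ar1: d² + d(d+1)/2 + d; random_walk: d(d+1)/2 + d;
static: d), and J is the Jacobian of the one-step EM operator at the
converged hyper-parameters, computed by central differences with relative
step 1e−4 (supplemented-EM style).  The BIC sample size R·T and the PDIO
step are package choices, exposed as arguments.

## Hypothesis testing

For sign-constraint regions of θ-space (a single higher-order parameter
positive, or a clique of simultaneously positive pairwise terms), the
bin-by-bin Bayes factor is the ratio of filter odds to one-step-prediction
odds of the two regions, reported in bits (log2); an epoch's weight of
evidence is the sum over its bins.  Region probabilities are Gaussian
orthant masses of the belief's marginal over the constrained coordinates:
closed form in 1-D, Genz's algorithm (scipy's multivariate normal CDF,
frozen seed, deterministic) up to 6 constrained dimensions.  Smoothed
beliefs are never used for Bayes factors — the factorization over bins is
a filtering construct.  Fits used for testing fix A = I, since an
autoregressive matrix optimized on a whole recording need not suit a
sub-interval.

Because verbal Bayes-factor calibrations are subjective, significance is
assessed by surrogates: fit the order-(k−1) null model to the epoch,
resample datasets from its smoothed MAP trajectory (preserving
time-varying rates and lower-order correlations, destroying the tested
order), recompute the order-k weight of evidence on each, and apply a
two-sided decision at the empirical (α/2, 1−α/2) quantiles (default 5%).
By default the innovation covariance is re-optimized on every surrogate
(`refit_hyper=True`); for large surrogate counts the `refit_hyper=False`
option freezes it at the value fitted to the original data, which is what
the calibration study below uses.

## Simulator

`ssll.simulate` draws patterns independently across trials and bins from
the exact per-bin distribution — precisely the sampling model the
likelihood assumes.  What it does **not** emulate: spike-history structure
(refractoriness, bursting), across-trial drift, and jitter in trial
alignment.  Passing tests therefore validate the estimator under its own
assumptions; on real data those assumptions must be checked separately
(e.g. split-half analyses across trials).

Named scenarios (magnitudes are constructor arguments, not constants):

- `pair_dynamic`: 2 neurons, constant rates (0.15/0.08 per bin), transient
  pairwise coupling bumps (height ~1.5).
- `independent_rate_mod`: 2 independent neurons, sinusoidal rate
  modulation — the classic false-positive control.
- `eight_neuron_pairwise`: 8 neurons, time-varying rates and pairwise
  couplings, no higher-order terms (m=2).
- `triple_dynamic`: 3 neurons with sinusoidal rate/pairwise trajectories
  and a triple-wise term that switches on in two epochs (amplitude ~1.2).
- `three_period_stationary`: three stationary periods with all per-bin
  rates fixed at 0.1: (I) independence; (II) positive pairwise couplings,
  θ_123=0, first-order θ solved so the rates stay 0.1; (III) θ_123=2.5
  with orders 1–2 solved (mixed-coordinate Newton) so pairwise joint rates
  sit exactly at the 0.01 chance level — the pairwise projection of period
  III is the independent model, while the triple-synchrony rate exceeds
  its 0.001 chance value.  The 0.1 per-bin rate is chosen to make that
  chance triple rate exactly 0.001.

`oracle_risk` provides truth-aware diagnostics (summed per-bin KL from the
true model to the estimate, and summed squared θ error, lower-order
estimates zero-padded) for simulator-side model-selection studies.

## Validation conditions (desk scale)

The acceptance suite runs at the following problem sizes, chosen once as
realistic desk-scale conditions:

- Parameter recovery: `triple_dynamic`, T=500 bins, R ∈ {50, 200, 500},
  10 seeds, random-walk EM (25 iterations); mean squared θ error must fall
  monotonically in R, and at R=500 the pointwise 99% bands must cover the
  truth in ≥ 90% of bins.
- Order selection: T=200 bins, R ∈ {20, 500}, 20 seeds, ar1 state model,
  candidates m ∈ {1,2,3}, generators of true order 2 (pairwise projection)
  and 3; AIC must pick m=1 at R=20 and the true order at R=500 in a
  majority of seeds.
- Surrogate test: 50-bin epochs; null calibration on stationary pairwise
  data (rates 0.1, θ_pair=0.4, R=50), 200 replicates, 200 surrogates,
  nominal 5% two-sided — empirical type-I error must lie in [2%, 9%];
  power on a sustained θ_123=1 (R=200) must reach ≥ 80% over 20 seeds.
  These runs use `refit_hyper=False` (hyper-parameters fitted once on the
  observed data, shared with surrogates).

## Known limitations

- Exact enumeration limits N (practically ≲ 10–12 for full higher-order
  analysis); no MCMC/mean-field approximations are provided.
- Bin width Δ is a free parameter; too small starves the higher-order
  statistics, too large blurs synchrony.  No data-driven Δ selection.
- Across-trial nonstationarity is not modeled; no trial-axis smoothing.
- EM ascent and credible intervals inherit the per-bin Gaussian (Laplace)
  approximation; the marginal likelihood is approximate, so information
  criteria compare approximations.
- Boundary conventions (half-open bins, boundary spikes to the later bin,
  partial last bin dropped) are package choices.
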