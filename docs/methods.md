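# Methods

This note records the models implemented, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
places where the design was genuinely open.

## Data and estimand

All borrowing analyses operate on two binomial arm summaries: the current
arm (y = 25 deaths of n = 106) and a historical arm (y_h = 95 of
n_h = 324). The estimand is the current-arm 28-day mortality rate θ.
The MAIC comparison additionally uses per-patient covariates (age, male
sex, any comorbidity) for the current arm and published covariate means
for the historical arm.

## Conjugate machinery

With θ ~ Beta(a, b) and a binomial likelihood, the posterior is
Beta(a + y, b + n − y). The prior effective sample size is m = a + b; the
posterior mean is (1 − λ)·prior mean + λ·(y/n) with shrinkage intensity
λ = m/(m + n). Two ESS conventions circulate: prior-only (m = a + b,
used for elicited priors) and pooled-analysis (m = a + b + n_h, counting
the historical patients the prior was built from). `prior_ess` defaults
to prior-only and exposes the other behind `include_historical_n`.

Quantile elicitation solves for (a, b) such that two Beta quantiles match
stated values (e.g. the 2.5th/97.5th percentiles matching a published
exact 95% CI of 0.24–0.35, giving ≈ Beta(76.8, 184.9)). Solver: damped
Newton on log-shapes, finite-difference Jacobian, residual tolerance
1e−8, 200 iterations max, moment-matched normal-approximation start.
Shapes are returned real-valued, not rounded to integers; downstream
means therefore differ from integer-rounded published values in the
fourth decimal.

Credible intervals are equal-tailed quantile intervals throughout, not
HPD (the published intervals match equal-tailed quantiles). Exact
binomial confidence intervals are Clopper–Pearson via beta quantiles.

Degenerate counts (y = 0 or y = n) are legal everywhere; only operations
that need a maximum-likelihood rate reject n = 0.

## Power priors

Fixed weight: the a₀-powered historical likelihood times a Beta initial
prior stays conjugate, Beta(a + a₀y_h + y, b + a₀(n_h−y_h) + n − y); the
prior component carries a + b + a₀·n_h pseudo-patients. The
empirical-Bayes weight maximizes the beta-binomial marginal likelihood of
the current data over a₀ ∈ [0, 1] (bounded Brent search, tolerance 1e−6,
endpoints checked; on these data â₀ = 0.5235).

Random weight: the joint density is taken as
L(D|θ) · L(D_h|θ)^{a₀} · π(a₀) · π(θ) — the *unnormalized* power prior.
Two implementation facts matter:

* The historical likelihood is the complete binomial pmf, **including its
  binomial coefficient**, raised to a₀. The coefficient is a large
  constant (log C(324,95) ≈ 193), so including it changes the a₀
  posterior drastically: with it, grid quadrature on these data gives
  E[a₀] ≈ 0.21 (consistent with the published ≈ 0.20); without it the a₀
  posterior collapses to ~0.005.
* A normalized-power-prior variant (renormalizing the powered likelihood
  over θ per a₀, where the coefficient cancels) is available behind the
  `normalized` flag; it is not the default.

Supported a₀ priors: Beta(p, q), exponential truncated to [0, 1], point
mass. The truncated exponential is rate-parameterized, so "rate 100"
gives a density ∝ e^{−100a₀}, essentially all mass below 0.05; a
*mean*-parameterized reading (rate 1/100, near-uniform) would instead
give E[a₀|data] ≈ 0.19 on these data. The rate parameterization is the
package's documented choice and the parameter is user-settable.

## Hierarchical (exchangeable) model

y ~ Bin(n, θ), y_h ~ Bin(n_h, θ_h), with θ, θ_h iid Beta(a_B, b_B). A
prior cannot be placed directly on the unbounded shape pair, so the hyper
level is parameterized by the mean μ_B = a_B/(a_B+b_B) (Beta prior,
default flat) and the concentration ν_B = a_B + b_B (default Uniform on
(0, 1000]). Large posterior ν_B means strong pooling of the two rates.

Sampling is collapsed: conditional on (μ_B, ν_B) the rates integrate out
analytically (beta-binomial marginals), so adaptive Metropolis runs on
(logit μ_B, log ν_B) only, and θ, θ_h are then drawn from their exact
conditional Beta posteriors for every retained state. A centered 4-D
random walk was rejected because it degenerates when ν_B is pinned large
(the rates ride a ridge of width ν_B^{−1/2}). The deterministic
reference (`hierarchical_quadrature`) evaluates the same analytic
marginal on a (μ, log ν) grid; on the published data it gives
E[θ|data] = 0.2677.

## Additive-bias (Pocock) model

y ~ Bin(n, θ), y_h ~ Bin(n_h, θ + δ_h), δ_h ~ N(μ, σ²), θ ~ Beta(1, 1).
σ is a standard deviation by default (`sigma_is_variance` available);
with σ = 0.03 the posterior δ_h spread matches the published interval
width, which a variance of 0.03 would not. Support violations
(θ + δ_h ∉ (0,1)) are handled by truncating the joint density (the
sampler rejects), never by clipping. σ → 0 with μ = 0 recovers full
pooling; large σ recovers the no-borrowing analysis; a fixed known bias
is the degenerate σ → 0 case with μ ≠ 0 rather than a separate code
path. The sampler runs on (logit θ, δ) with per-coordinate scales from
the prior-plus-Fisher precision of δ, so near-degenerate σ mixes
properly. `pocock_bias_quadrature` is the dense 2-D grid reference.

## MCMC engine

All samplers share one adaptive random-walk Metropolis core: 4 chains,
10,000 retained draws each after 2,000 burn-in by default, multivariate
normal proposals whose covariance adapts (Haario-style running
covariance plus Robbins–Monro global scale targeting 0.30 acceptance)
during burn-in only, frozen afterwards. Convergence is monitored by
split-R̂; results attach a diagnostic warning at R̂ ≥ 1.05, and the test
suite requires R̂ < 1.01. Every run is exactly reproducible from one
integer seed; conditional draws use a sub-stream derived from it.

Each MCMC model has a deterministic quadrature reference implemented
alongside it, and the test suite requires sampler/quadrature agreement
within 0.005 on posterior means.

## MAIC

Weights take the exponential-tilt form w_i = exp((x_i − x̄_target)ᵀβ);
β minimizes the convex objective Σ_i exp((x_i − x̄_target)ᵀβ), whose
gradient is the moment condition Σ_i w_i (x_i − x̄_target) = 0.
Covariates are standardized internally for conditioning (β is reported
on the original scale); BFGS with analytic gradient, gradient tolerance
1e−10·n. Only **means** of age, male and comorbidity are matched — the
published weighted age SD equals the unweighted one, indicating variances
were not matched. Infeasible targets (outside the covariate convex hull)
raise an error naming the offending covariate. Diagnostics: Kish
effective sample size (Σw)²/Σw² and a near-zero-weight count.

Outcome comparison: the historical arm is reconstructed as y_h
unit-weight event rows and n_h − y_h non-event rows (its counts fully
determine it; it has no covariates by construction), stacked with the
weighted IPD rows, and a weighted logistic regression of outcome on a
treatment indicator is fitted with a heteroskedasticity-robust (HC0
sandwich) covariance for the CI. With an intercept-plus-indicator design
the weighted MLE has the closed form of the weighted odds ratio; the
bootstrap uses that identity per replicate (proven equal to the GLM route
in the tests) for speed. The bootstrap resamples IPD patients with
replacement, re-estimates the weights in each replicate (1,000 replicates by
default — the published analysis states neither the count nor whether
weights were re-estimated), and reports the median and equal-tailed
percentile interval; replicates that fail to converge are dropped, with
an error if more than 10% do.

Non-collapsibility note: the weighted OR targets the *marginal*
treatment OR in the target population, which differs from the
conditional (covariate-adjusted) log-OR coefficient whenever covariate
effects are nonzero. The parameter-recovery test therefore computes its
oracle — the marginal OR in the comparator population — by Monte Carlo
from the generating model rather than reusing the conditional
coefficient.

## Synthetic data generator

Emulates the published current-arm table: age from N(66.1, 10.7²)
truncated at 18 years (adult eligibility), male ~ Bernoulli(0.804),
comorbidity ~ Bernoulli(0.701), death from a logistic model whose
intercept is calibrated by 1-D root finding on a 200,000-point
Monte-Carlo estimate of the marginal rate (target 25/106 ≈ 0.236).
Covariates are independent by default — no correlation structure is
published — with an optional Gaussian-copula age–comorbidity correlation
for sensitivity studies. Default outcome coefficients (log-OR 0.05 per
year of age, 0.3 for male, 0.5 for comorbidity) are plausible magnitudes
chosen by the implementer; they are synthetic and not estimated from any
trial.

What passing tests on this generator do **not** show: anything about the
real per-patient data (which is not public). In particular, the published
weighted OR of 0.415, bootstrap median 0.413 and mean weight 0.7362
depend on the real IPD and are documented as non-reproducible; the MAIC
machinery is instead validated by its defining moment-matching property,
closed-form equivalences, and parameter recovery on data with a known
generating effect.

## Known discrepancies with the published table

Two published results cannot be produced by the models as stated, as
verified by exact grid quadrature (not just MCMC):

* **Bias model.** The published table prints θ̄ = 0.2770 for all three
  bias priors (μ = 0, ±0.07, σ = 0.03). Exact quadrature of the stated
  model gives 0.2687, 0.2310 and 0.3098 respectively — a ±0.07 prior
  bias shift of the historical rate must move θ, and the printed δ_h
  rows for these cases are themselves sign-inconsistent. The package
  reports the model-correct values; for μ = 0 they are within 0.01 of
  the printed one.
* **Hierarchical model.** The printed θ̄ = 0.2944 exceeds even the
  historical ML rate (0.2932), which no amount of shrinkage between
  0.236 and 0.293 can produce; under this package's hyperprior the exact
  value is 0.2677. (The printed value is close to the *historical* rate's
  posterior mean, suggesting a reported θ_h or a labeling slip.) The
  hyperprior interpretation is itself open — the source text places
  "Beta(1,1)" on the shapes a_B, b_B directly, which would give ≈ 0.241
  for θ — and the mean/concentration parameterization used here is the
  standard weakly-informative resolution.

The corresponding assertions in `tests/test_acceptance.py` state the
published values at face value and fail; they are kept failing rather
than weakened.

## Problem sizes

Defaults were chosen so a full analysis runs in seconds on one core:
4×10,000 MCMC draws per model, 400×400 quadrature grids (2,000×2,000 for
the 2-D bias reference), 1,000 bootstrap replicates, 200,000-point
calibration draws. The parameter-recovery study in the test suite uses
100 replicates of n = 250 patients with 200 bootstrap replicates each.
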