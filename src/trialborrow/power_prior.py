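"""Power-prior borrowing of a historical binomial arm.

The power prior discounts the historical arm by raising its likelihood to
an exponent ``a0 in [0, 1]``: a0=0 ignores the external data, a0=1 pools
it at full weight, and intermediate values borrow the information of
roughly ``a0 * n_h`` historical patients.  With a Beta initial prior the
fixed-a0 posterior stays conjugate:

    Beta(a + a0*y_h + y,  b + a0*(n_h - y_h) + (n - y)).

Three ways of handling a0 are provided:

* a fixed, user-chosen a0 (including a grid profile over [0, 1]);
* empirical-Bayes selection, maximizing the marginal likelihood of the
  current data over a0;
* a fully Bayesian random a0 with a prior on [0, 1], sampled jointly with
  the rate by MCMC and cross-checked by dense 2-D grid quadrature.

The random-a0 joint density uses the complete historical binomial pmf
(including its binomial coefficient) raised to a0; because the coefficient
is a constant much larger than the pmf's kernel, omitting it changes the
a0 posterior drastically.  A normalized-power-prior variant (renormalizing
the powered likelihood over the rate for each a0) is available behind the
``normalized`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from ._mcmc import run_chains, summarize_draws
from .conjugate import (
    BetaParams,
    BinomialSummary,
    PosteriorResult,
    beta_binomial_update,
    posterior_summary,
)

__all__ = [
    "A0Prior",
    "PowerPriorConfig",
    "fixed_a0_posterior",
    "log_marginal_likelihood_a0",
    "empirical_bayes_a0",
    "random_a0_posterior",
    "random_a0_quadrature",
    "a0_profile",
]


@dataclass(frozen=True)
class A0Prior:
    """Prior for a random power-prior weight a0, supported on [0, 1].

    Families: ``beta(p, q)``; ``truncexp(rate)`` (exponential truncated to
    [0, 1]; positive rate gives a density decreasing in a0); ``point(v)``
    (degenerate, reduces to the fixed-a0 analysis).
    """

    family: str
    params: tuple

    def __post_init__(self) -> None:
        fam = self.family.lower()
        if fam not in {"beta", "truncexp", "point"}:
            raise ValueError(f"unsupported a0 prior family: {self.family!r}")
        object.__setattr__(self, "family", fam)
        if fam == "beta":
            p, q = self.params
            if not (p > 0 and q > 0):
                raise ValueError(f"beta prior shapes must be positive, got {self.params}")
        elif fam == "truncexp":
            (rate,) = self.params
            if rate == 0:
                raise ValueError("truncated-exponential rate must be nonzero")
        elif fam == "point":
            (v,) = self.params
            if not 0 <= v <= 1:
                raise ValueError(f"point mass must lie in [0, 1], got {v}")

    def logpdf(self, a0: np.ndarray) -> np.ndarray:
        a0 = np.asarray(a0, dtype=float)
        if self.family == "beta":
            p, q = self.params
            return stats.beta.logpdf(a0, p, q)
        if self.family == "truncexp":
            (rate,) = self.params
            lognorm = np.log(-np.expm1(-rate)) - np.log(rate) if rate > 0 else \
                np.log(np.expm1(-rate) / -rate)
            out = np.where((a0 >= 0) & (a0 <= 1), -rate * a0 - lognorm, -np.inf)
            return out
        raise ValueError("point-mass prior has no density")


@dataclass(frozen=True)
class PowerPriorConfig:
    """Initial prior for the rate plus the treatment of the weight a0."""

    initial_prior: BetaParams = field(default_factory=lambda: BetaParams(1.0, 1.0))
    a0: float | A0Prior = 1.0
    normalized: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.a0, A0Prior):
            if not 0 <= self.a0 <= 1:
                raise ValueError(f"fixed a0 must lie in [0, 1], got {self.a0}")


def _require_fixed(cfg: PowerPriorConfig) -> float:
    if isinstance(cfg.a0, A0Prior):
        if cfg.a0.family == "point":
            return cfg.a0.params[0]
        raise ValueError("this operation requires a fixed a0, not a distribution")
    return float(cfg.a0)


def fixed_a0_posterior(
    cfg: PowerPriorConfig, data: BinomialSummary, hist: BinomialSummary
) -> BetaParams:
    """Conjugate posterior with the historical arm down-weighted by a fixed a0."""
    a0 = _require_fixed(cfg)
    prior = cfg.initial_prior
    powered = BetaParams(prior.a + a0 * hist.deaths, prior.b + a0 * hist.survivors)
    return beta_binomial_update(powered, data)


def log_marginal_likelihood_a0(
    cfg: PowerPriorConfig,
    data: BinomialSummary,
    hist: BinomialSummary,
    a0: float,
) -> float:
    """Log marginal likelihood of the current data under the a0-powered prior.

    ``log m(a0) = log C(n, y) + log B(A + y, B + n - y) - log B(A, B)`` with
    ``A = a + a0*y_h``, ``B = b + a0*(n_h - y_h)``: the beta-binomial
    predictive of the current arm given the powered historical prior.
    """
    if not 0 <= a0 <= 1:
        raise ValueError(f"a0 must lie in [0, 1], got {a0}")
    A = cfg.initial_prior.a + a0 * hist.deaths
    B = cfg.initial_prior.b + a0 * hist.survivors
    y, n = data.deaths, data.n
    const = special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
    return float(const + special.betaln(A + y, B + n - y) - special.betaln(A, B))


def empirical_bayes_a0(
    cfg: PowerPriorConfig,
    data: BinomialSummary,
    hist: BinomialSummary,
    tol: float = 1e-6,
) -> float:
    """Empirical-Bayes weight: argmax over [0, 1] of the marginal likelihood.

    Bounded scalar optimization; boundary solutions (no borrowing / full
    pooling) are legitimate answers, so the two endpoints are compared
    against the interior optimum.
    """
    neg = lambda a0: -log_marginal_likelihood_a0(cfg, data, hist, a0)
    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": tol})
    candidates = [(neg(0.0), 0.0), (neg(1.0), 1.0), (res.fun, float(res.x))]
    return min(candidates)[1]


def a0_profile(
    cfg: PowerPriorConfig,
    data: BinomialSummary,
    hist: BinomialSummary,
    grid,
    level: float = 0.95,
) -> list[tuple[float, PosteriorResult]]:
    """Fixed-a0 posterior summaries along a grid of weights (sensitivity curve)."""
    out = []
    for a0 in np.asarray(grid, dtype=float):
        cfg_i = PowerPriorConfig(cfg.initial_prior, float(a0), cfg.normalized)
        params = fixed_a0_posterior(cfg_i, data, hist)
        out.append((float(a0), posterior_summary(params, level)))
    return out


def _joint_log_density_parts(cfg, data, hist):
    """Pieces of the joint (theta, a0) log density shared by MCMC and quadrature."""
    y, n = data.deaths, data.n
    yh, nh = hist.deaths, hist.n
    a, b = cfg.initial_prior.a, cfg.initial_prior.b
    log_choose_h = (special.gammaln(nh + 1) - special.gammaln(yh + 1)
                    - special.gammaln(nh - yh + 1))

    def log_joint(theta, a0, log_prior_a0):
        lt, l1t = np.log(theta), np.log1p(-theta)
        lp = (y * lt + (n - y) * l1t
              + a0 * (yh * lt + (nh - yh) * l1t + log_choose_h)
              + (a - 1) * lt + (b - 1) * l1t
              + log_prior_a0)
        if cfg.normalized:
            # renormalize the powered historical likelihood over theta per a0
            lp -= special.betaln(a + a0 * yh, b + a0 * (nh - yh)) - special.betaln(a, b)
        return lp

    return log_joint


def random_a0_posterior(
    cfg: PowerPriorConfig,
    data: BinomialSummary,
    hist: BinomialSummary,
    n_draws: int = 10_000,
    seed: int = 0,
    n_chains: int = 4,
    burn: int = 2_000,
    level: float = 0.95,
) -> PosteriorResult:
    """Joint posterior of (theta, a0) under a random power-prior weight, by MCMC.

    Adaptive random-walk Metropolis on (logit theta, logit a0).  The result
    summarizes theta, with the a0 summary under ``aux['a0']`` and pooled
    draws for both parameters.
    """
    if not isinstance(cfg.a0, A0Prior):
        raise ValueError("random_a0_posterior requires an A0Prior distribution spec")
    if cfg.a0.family == "point":
        params = fixed_a0_posterior(cfg, data, hist)
        res = posterior_summary(params, level)
        res.aux["a0"] = {"mean": cfg.a0.params[0], "median": cfg.a0.params[0],
                         "ci_low": cfg.a0.params[0], "ci_high": cfg.a0.params[0],
                         "level": level}
        return res

    log_joint = _joint_log_density_parts(cfg, data, hist)
    prior_a0 = cfg.a0

    def log_post(x):
        lt, la = x[..., 0], x[..., 1]
        theta = special.expit(lt)
        a0 = special.expit(la)
        lp = log_joint(theta, a0, prior_a0.logpdf(a0))
        # Jacobians of the logit transforms
        lp += np.log(theta) + np.log1p(-theta) + np.log(a0) + np.log1p(-a0)
        return lp

    x0 = np.array([special.logit(max(data.rate, 1e-3)), special.logit(0.5)])
    draws_u, info = run_chains(log_post, x0, n_chains=n_chains, n_draws=n_draws,
                               burn=burn, seed=seed, scales=np.array([0.3, 1.0]))
    theta = special.expit(draws_u[:, :, 0]).ravel()
    a0 = special.expit(draws_u[:, :, 1]).ravel()

    s = summarize_draws(theta, level)
    res = PosteriorResult(**s)
    res.aux["a0"] = summarize_draws(a0, level)
    res.draws = {"theta": theta, "a0": a0}
    res.diagnostics = {"rhat": dict(zip(["theta", "a0"], info["rhat"].tolist())),
                       "accept_rate": info["accept_rate"].tolist(),
                       "seed": seed}
    return res


def random_a0_quadrature(
    cfg: PowerPriorConfig,
    data: BinomialSummary,
    hist: BinomialSummary,
    n_theta: int = 400,
    n_a0: int = 400,
    level: float = 0.95,
) -> PosteriorResult:
    """Deterministic reference for :func:`random_a0_posterior` by 2-D grid quadrature.

    Midpoint rule on a (theta, a0) grid; marginal means and equal-tailed
    intervals are read off the normalized grid masses.
    """
    if not isinstance(cfg.a0, A0Prior) or cfg.a0.family == "point":
        raise ValueError("quadrature reference requires a continuous a0 prior")
    theta = (np.arange(n_theta) + 0.5) / n_theta
    a0 = (np.arange(n_a0) + 0.5) / n_a0
    TH, A0 = np.meshgrid(theta, a0, indexing="ij")
    log_joint = _joint_log_density_parts(cfg, data, hist)
    lp = log_joint(TH, A0, cfg.a0.logpdf(A0))
    lp -= lp.max()
    P = np.exp(lp)
    P /= P.sum()

    def marginal_summary(axis_vals, mass):
        mean = float(np.sum(axis_vals * mass))
        cdf = np.cumsum(mass)
        alpha = (1 - level) / 2
        lo, med, hi = np.interp([alpha, 0.5, 1 - alpha], cdf, axis_vals)
        return {"mean": mean, "median": float(med), "ci_low": float(lo),
                "ci_high": float(hi), "level": level}

    s_theta = marginal_summary(theta, P.sum(axis=1))
    s_a0 = marginal_summary(a0, P.sum(axis=0))
    res = PosteriorResult(**s_theta)
    res.aux["a0"] = s_a0
    res.diagnostics = {"method": "grid-quadrature", "n_theta": n_theta, "n_a0": n_a0}
    return res
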