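"""Closed-form beta-binomial machinery for borrowing historical arm data.

The endpoint throughout is a binomial event rate ``theta`` (here: 28-day
mortality in a dexamethasone arm).  A ``Beta(a, b)`` prior is conjugate to
the binomial likelihood, so every operation in this module is exact: the
posterior after observing ``y`` events in ``n`` patients is
``Beta(a + y, b + n - y)``, the prior carries an effective sample size
``m = a + b`` pseudo-patients, and the posterior mean is the shrinkage
combination ``(1 - lambda) * prior_mean + lambda * y/n`` with
``lambda = n / (a + b + n)``.

Borrowing a historical arm ``(y_h, n_h)`` at full weight is a second
conjugate update (pooling); partial borrowing by prior elicitation
(quantile matching, or mean plus effective sample size) is also closed
form.  Down-weighted borrowing lives in :mod:`trialborrow.power_prior`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BinomialSummary",
    "BetaParams",
    "PosteriorResult",
    "ConvergenceError",
    "beta_binomial_update",
    "pooled_posterior",
    "elicit_beta_from_quantiles",
    "beta_from_mean_ess",
    "prior_ess",
    "shrinkage_intensity",
    "exact_binomial_ci",
    "posterior_summary",
]


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance."""


@dataclass(frozen=True)
class BinomialSummary:
    """Aggregate outcome of one trial arm: ``deaths`` events in ``n`` patients."""

    deaths: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 0 or int(self.n) != self.n:
            raise ValueError(f"sample size must be a non-negative integer, got {self.n}")
        if self.deaths < 0 or int(self.deaths) != self.deaths:
            raise ValueError(f"event count must be a non-negative integer, got {self.deaths}")
        if self.deaths > self.n:
            raise ValueError(f"deaths ({self.deaths}) cannot exceed n ({self.n})")

    @property
    def survivors(self) -> int:
        return self.n - self.deaths

    @property
    def rate(self) -> float:
        """Maximum-likelihood event rate y/n."""
        if self.n == 0:
            raise ValueError("rate undefined for an empty arm (n=0)")
        return self.deaths / self.n


@dataclass(frozen=True)
class BetaParams:
    """Shape pair of a Beta distribution used as prior or posterior for a rate."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and np.isfinite(self.a)):
            raise ValueError(f"shape a must be positive and finite, got {self.a}")
        if not (self.b > 0 and np.isfinite(self.b)):
            raise ValueError(f"shape b must be positive and finite, got {self.b}")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def ess(self) -> float:
        """Effective sample size ``a + b``: pseudo-patients carried by the prior."""
        return self.a + self.b

    def quantile(self, p):
        return stats.beta.ppf(p, self.a, self.b)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b}


@dataclass
class PosteriorResult:
    """Posterior summary for the event rate, with optional draws and auxiliaries.

    ``mean``/``median``/``ci_low``/``ci_high`` summarize the primary
    parameter (the current-trial rate theta) with an equal-tailed interval
    at ``level``.  ``params`` is set when the posterior is conjugate Beta.
    ``aux`` maps auxiliary parameter names (e.g. ``a0``, ``delta_h``) to
    summary dicts; ``draws`` maps parameter names to pooled MCMC draws;
    ``diagnostics`` carries sampler metadata (split-Rhat, acceptance).
    """

    mean: float
    median: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    params: BetaParams | None = None
    aux: dict = field(default_factory=dict)
    draws: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def beta_binomial_update(prior: BetaParams, data: BinomialSummary) -> BetaParams:
    """Conjugate update: ``Beta(a, b)`` + ``y/n`` -> ``Beta(a + y, b + n - y)``."""
    return BetaParams(prior.a + data.deaths, prior.b + data.survivors)


def pooled_posterior(
    prior: BetaParams, data: BinomialSummary, hist: BinomialSummary
) -> BetaParams:
    """Full-weight borrowing: both arms enter the conjugate update at weight one.

    Equivalent to using the historical posterior as the prior for the
    current arm; the two sequential updates commute.
    """
    return beta_binomial_update(beta_binomial_update(prior, hist), data)


def posterior_summary(params: BetaParams, level: float = 0.95) -> PosteriorResult:
    """Mean, median and equal-tailed credible interval of a Beta posterior."""
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = (1 - level) / 2
    lo, med, hi = stats.beta.ppf([alpha, 0.5, 1 - alpha], params.a, params.b)
    return PosteriorResult(
        mean=params.mean, median=float(med), ci_low=float(lo), ci_high=float(hi),
        level=level, params=params,
    )


def elicit_beta_from_quantiles(
    p_lo: float,
    q_lo: float,
    p_hi: float,
    q_hi: float,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> BetaParams:
    """Solve for Beta shapes whose ``p_lo``/``p_hi`` quantiles equal ``q_lo``/``q_hi``.

    Two-dimensional damped Newton iteration on the log-shape scale
    (finite-difference Jacobian); the returned shapes are real-valued.
    Used to turn a published rate estimate with its exact 95% CI (e.g.
    0.24-0.35 for the historical arm) into an informative prior.
    """
    if not (0 < p_lo < p_hi < 1):
        raise ValueError(f"quantile levels must satisfy 0 < p_lo < p_hi < 1, got {p_lo}, {p_hi}")
    if not (0 < q_lo < q_hi < 1):
        raise ValueError(f"quantile values must satisfy 0 < q_lo < q_hi < 1, got {q_lo}, {q_hi}")

    # moment-matched starting point: normal approximation to the interval
    z = stats.norm.ppf([p_lo, p_hi])
    m0 = (q_lo + q_hi) / 2
    s0 = max((q_hi - q_lo) / (z[1] - z[0]), 1e-4)
    ess0 = max(m0 * (1 - m0) / s0**2 - 1, 0.5)
    x = np.log([m0 * ess0, (1 - m0) * ess0])

    def resid(x):
        a, b = np.exp(x)
        return np.array(
            [stats.beta.ppf(p_lo, a, b) - q_lo, stats.beta.ppf(p_hi, a, b) - q_hi]
        )

    r = resid(x)
    for _ in range(max_iter):
        if np.max(np.abs(r)) < tol:
            a, b = np.exp(x)
            return BetaParams(float(a), float(b))
        # finite-difference Jacobian in log shapes
        J = np.empty((2, 2))
        h = 1e-6
        for j in range(2):
            xp = x.copy()
            xp[j] += h
            J[:, j] = (resid(xp) - r) / h
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Jacobian at shapes {np.exp(x)}") from exc
        # damping: halve until the residual norm decreases
        lam, ok = 1.0, False
        for _ in range(30):
            r_new = resid(x + lam * step)
            if np.linalg.norm(r_new) < np.linalg.norm(r):
                x, r, ok = x + lam * step, r_new, True
                break
            lam /= 2
        if not ok:
            x = x + lam * step
            r = resid(x)
    if np.max(np.abs(r)) < tol:
        a, b = np.exp(x)
        return BetaParams(float(a), float(b))
    raise ConvergenceError(
        f"quantile elicitation did not converge in {max_iter} iterations; "
        f"residuals {r.tolist()} at shapes {np.exp(x).tolist()}"
    )


def beta_from_mean_ess(mean: float, m: float) -> BetaParams:
    """Prior from a target mean and effective sample size: ``Beta(mean*m, (1-mean)*m)``.

    The standard way to down-weight an external arm: keep its observed rate
    as the prior mean but assign it only ``m`` pseudo-patients.
    """
    if not 0 < mean < 1:
        raise ValueError(f"prior mean must be in (0, 1), got {mean}")
    if not m > 0:
        raise ValueError(f"effective sample size must be positive, got {m}")
    return BetaParams(mean * m, m - mean * m)


def prior_ess(prior: BetaParams, hist_n: int = 0, include_historical_n: bool = False) -> float:
    """Effective sample size of a Beta prior, ``a + b``.

    With ``include_historical_n`` the pooled-analysis convention
    ``a + b + n_h`` is returned instead (the prior plus the historical
    patients it was combined with); the default is prior-only.
    """
    m = prior.ess
    if include_historical_n:
        m += hist_n
    return m


def shrinkage_intensity(m: float, n: int) -> float:
    """Weight ``lambda = m / (m + n)`` of the prior in the posterior-mean blend.

    The posterior mean equals ``(1 - lambda) * (y/n) + lambda * prior_mean``
    when ``m`` is the prior ESS; equivalently the data's weight is
    ``n / (m + n)``.
    """
    if m < 0:
        raise ValueError(f"effective sample size must be non-negative, got {m}")
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    return m / (m + n)


def exact_binomial_ci(data: BinomialSummary, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson equal-tailed exact confidence interval for a binomial rate.

    Beta-quantile form: lower bound ``Beta^{-1}(alpha/2; y, n-y+1)`` (0 when
    y=0), upper bound ``Beta^{-1}(1-alpha/2; y+1, n-y)`` (1 when y=n).
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if data.n == 0:
        raise ValueError("confidence interval undefined for an empty arm (n=0)")
    alpha = 1 - level
    y, n = data.deaths, data.n
    lo = 0.0 if y == 0 else float(stats.beta.ppf(alpha / 2, y, n - y + 1))
    hi = 1.0 if y == n else float(stats.beta.ppf(1 - alpha / 2, y + 1, n - y))
    return lo, hi
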