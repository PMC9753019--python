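"""Matching-adjusted indirect comparison (MAIC) for one IPD arm vs. an aggregate arm.

The individual-patient-data (IPD) arm is reweighted so that its weighted
covariate means equal the published means of the comparator population.
Weights take the exponential-tilt (propensity-score logistic) form

    w_i = exp((x_i - x_target)' beta),

with beta chosen by the method of moments: minimizing the convex objective
``sum_i exp((x_i - x_target)' beta)`` whose gradient is exactly the
estimating equation ``sum_i w_i (x_i - x_target) = 0``.  At the optimum
the weighted means reproduce the targets to solver precision.

Outcomes are then compared across the combined pseudo-population (weighted
IPD rows plus the aggregate arm reconstructed as unit-weight binary rows)
with a weighted logistic regression on a treatment indicator; a
heteroskedasticity-robust ("sandwich") covariance yields the confidence
interval, and a patient-level bootstrap (re-estimating the weights in each
replicate) provides a percentile alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.stats.contingency_tables import Table2x2

from .conjugate import BinomialSummary, ConvergenceError

__all__ = [
    "MATCH_COLUMNS",
    "AggregateTargets",
    "ORResult",
    "MAICResult",
    "validate_ipd",
    "estimate_weights",
    "rescale_weights",
    "weight_diagnostics",
    "unadjusted_or",
    "weighted_or",
    "bootstrap_or",
]

MATCH_COLUMNS = ("age", "male", "comorbidity")
OUTCOME_COLUMN = "death28"


@dataclass(frozen=True)
class AggregateTargets:
    """Published covariate means of the comparator arm (aggregate-only trial)."""

    age_mean: float
    male_prop: float
    comorbidity_prop: float

    def __post_init__(self) -> None:
        for name in ("male_prop", "comorbidity_prop"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.age_mean, self.male_prop, self.comorbidity_prop])


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with an equal-tailed interval at ``level``."""

    oddsratio: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = ""


@dataclass
class MAICResult:
    """Weights, balance diagnostics and (optionally) outcome comparisons."""

    weights: np.ndarray
    weights_rescaled: np.ndarray
    beta: np.ndarray
    balance: pd.DataFrame
    ess_weights: float
    near_zero_count: int
    or_unadjusted: ORResult | None = None
    or_weighted: ORResult | None = None
    or_bootstrap: ORResult | None = None


def validate_ipd(ipd: pd.DataFrame, require_outcome: bool = True) -> pd.DataFrame:
    """Check the IPD table has the matched covariates, no missingness, valid binaries."""
    cols = list(MATCH_COLUMNS) + ([OUTCOME_COLUMN] if require_outcome else [])
    missing = [c for c in cols if c not in ipd.columns]
    if missing:
        raise ValueError(f"IPD table lacks required columns: {missing}")
    if len(ipd) == 0:
        raise ValueError("IPD table is empty")
    if ipd[cols].isna().any().any():
        raise ValueError("IPD table contains missing values in matched/outcome columns")
    for c in cols:
        if c == "age":
            continue
        vals = set(np.unique(ipd[c].to_numpy()))
        if not vals <= {0, 1}:
            raise ValueError(f"column {c!r} must be binary 0/1, found values {sorted(vals)}")
    return ipd


def rescale_weights(weights: np.ndarray) -> np.ndarray:
    """Scale weights so they average exactly one (pure presentation; all
    weighted means and odds ratios are invariant to a positive rescaling)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    mean = w.mean()
    if mean <= 0:
        raise ValueError("cannot rescale all-zero weights")
    return w / mean


def weight_diagnostics(weights: np.ndarray, near_zero_threshold: float = 0.01):
    """Kish effective sample size ``(sum w)^2 / sum w^2`` and the count of
    weights below ``threshold * mean(w)`` (patients effectively dropped)."""
    w = np.asarray(weights, dtype=float)
    ess = float(w.sum() ** 2 / np.sum(w**2))
    near_zero = int(np.sum(w < near_zero_threshold * w.mean()))
    return ess, near_zero


def _weighted_sd(x: np.ndarray, w: np.ndarray) -> float:
    m = np.average(x, weights=w)
    return float(np.sqrt(np.average((x - m) ** 2, weights=w)))


def estimate_weights(
    ipd: pd.DataFrame,
    targets: AggregateTargets,
    tol: float = 1e-10,
    near_zero_threshold: float = 0.01,
) -> MAICResult:
    """Method-of-moments MAIC weights matching covariate MEANS to the targets.

    Covariates are standardized internally for conditioning; ``beta`` is
    reported on the original scale.  Raises :class:`ConvergenceError`
    naming the worst-matched covariate when the targets are infeasible
    (outside the convex hull of the IPD covariates).
    """
    validate_ipd(ipd, require_outcome=False)
    X = ipd[list(MATCH_COLUMNS)].to_numpy(dtype=float)
    t = targets.as_array()
    Xc = X - t
    scale = X.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    Xs = Xc / scale

    def fgrad(b):
        w = np.exp(Xs @ b)
        return w.sum(), Xs.T @ w

    res = optimize.minimize(
        fgrad, np.zeros(X.shape[1]), jac=True, method="BFGS",
        options={"gtol": tol * len(ipd), "maxiter": 500},
    )
    w = np.exp(Xs @ res.x)
    wm = (w @ X) / w.sum()
    err = np.abs(wm - t) / np.maximum(np.abs(t), 1.0)
    if not np.all(err < 1e-6):
        outside = [c for j, c in enumerate(MATCH_COLUMNS)
                   if not X[:, j].min() <= t[j] <= X[:, j].max()]
        j = int(np.argmax(err))
        culprit = ", ".join(outside) if outside else MATCH_COLUMNS[j]
        raise ConvergenceError(
            f"moment matching failed for covariate(s) {culprit} "
            f"(worst weighted mean {wm[j]:.4f} vs target {t[j]:.4f}); "
            "targets may lie outside the convex hull of the IPD covariates"
        )

    w_res = rescale_weights(w)
    ess, nzero = weight_diagnostics(w, near_zero_threshold)
    balance = pd.DataFrame(
        {
            "ipd_mean": X.mean(axis=0),
            "ipd_sd": X.std(axis=0, ddof=1),
            "weighted_mean": wm,
            "weighted_sd": [_weighted_sd(X[:, j], w) for j in range(X.shape[1])],
            "target": t,
        },
        index=list(MATCH_COLUMNS),
    )
    return MAICResult(
        weights=w, weights_rescaled=w_res, beta=res.x / scale,
        balance=balance, ess_weights=ess, near_zero_count=nzero,
    )


def unadjusted_or(
    curr: BinomialSummary, hist: BinomialSummary, level: float = 0.95
) -> ORResult:
    """Odds ratio of death (current vs. historical arm) from the 2x2 counts,
    with the Wald interval on the log scale."""
    cells = np.array(
        [[curr.deaths, curr.survivors], [hist.deaths, hist.survivors]], dtype=float
    )
    if np.any(cells == 0):
        raise ValueError(
            "a zero cell makes the Wald odds-ratio interval undefined; "
            "consider a continuity correction (not applied by default)"
        )
    table = Table2x2(cells)
    lo, hi = table.oddsratio_confint(alpha=1 - level)
    return ORResult(float(table.oddsratio), float(lo), float(hi), level, "wald")


def _pseudo_population(ipd: pd.DataFrame, weights: np.ndarray, hist: BinomialSummary):
    """Stack weighted IPD rows (treat=1) with reconstructed historical rows (treat=0)."""
    from .synthetic import reconstruct_binary_arm

    y_curr = ipd[OUTCOME_COLUMN].to_numpy(dtype=float)
    y_hist = reconstruct_binary_arm(hist)[OUTCOME_COLUMN].to_numpy(dtype=float)
    endog = np.concatenate([y_curr, y_hist])
    treat = np.concatenate([np.ones_like(y_curr), np.zeros_like(y_hist)])
    w = np.concatenate([np.asarray(weights, dtype=float), np.ones_like(y_hist)])
    return endog, treat, w


def _check_separation(endog, treat, w):
    for arm in (0, 1):
        mask = treat == arm
        rate = np.average(endog[mask], weights=w[mask])
        if rate in (0.0, 1.0):
            raise ValueError(
                f"separation: weighted event rate in arm treat={arm} is {rate:g}; "
                "the odds ratio is not identified"
            )


def weighted_or(
    ipd: pd.DataFrame,
    weights: np.ndarray,
    hist: BinomialSummary,
    level: float = 0.95,
    cov_type: str = "HC0",
) -> ORResult:
    """Weighted logistic regression of outcome on treatment over the combined
    pseudo-population, with a sandwich-covariance confidence interval.

    The historical arm enters as ``y_h`` unit-weight event rows and
    ``n_h - y_h`` non-event rows (its counts fully determine it); the IPD
    arm carries the MAIC weights.  The point estimate is invariant to a
    positive rescaling of the weights.
    """
    validate_ipd(ipd)
    if len(weights) != len(ipd):
        raise ValueError("one weight per IPD row is required")
    endog, treat, w = _pseudo_population(ipd, weights, hist)
    _check_separation(endog, treat, w)
    exog = sm.add_constant(treat)
    fit = sm.GLM(endog, exog, family=sm.families.Binomial(), freq_weights=w).fit(
        cov_type=cov_type
    )
    coef = fit.params[1]
    se = fit.bse[1]
    z = stats.norm.ppf(1 - (1 - level) / 2)
    return ORResult(
        float(np.exp(coef)), float(np.exp(coef - z * se)), float(np.exp(coef + z * se)),
        level, f"weighted-logistic+{cov_type}",
    )


def _weighted_or_point(y: np.ndarray, w: np.ndarray, hist: BinomialSummary) -> float:
    """Closed-form MLE of the weighted two-arm logistic model.

    With only an intercept and a treatment indicator the weighted score
    equations saturate, so the fitted arm rates are the weighted event
    rates and the OR is the weighted odds ratio.  Identical to the GLM
    route (asserted in the test suite); used inside the bootstrap for speed.
    """
    p1 = np.average(y, weights=w)
    p0 = hist.rate
    if p1 in (0.0, 1.0) or p0 in (0.0, 1.0):
        raise ValueError("separation in a bootstrap replicate")
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


def bootstrap_or(
    ipd: pd.DataFrame,
    targets: AggregateTargets,
    hist: BinomialSummary,
    reps: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_failure_frac: float = 0.10,
) -> ORResult:
    """Patient-level bootstrap of the MAIC-weighted odds ratio.

    Each replicate resamples IPD rows with replacement, re-estimates the
    weights, and recomputes the weighted OR; the median and equal-tailed
    percentile interval are reported.  Replicates whose weight fit fails
    are dropped (error if more than ``max_failure_frac`` do).
    """
    if reps < 100:
        raise ValueError(f"reps must be >= 100, got {reps}")
    validate_ipd(ipd)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(ipd)
    ors = []
    failures = 0
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        boot = ipd.iloc[idx]
        try:
            fit = estimate_weights(boot, targets)
            ors.append(_weighted_or_point(
                boot[OUTCOME_COLUMN].to_numpy(dtype=float), fit.weights, hist))
        except (ConvergenceError, ValueError):
            failures += 1
    if failures > max_failure_frac * reps:
        raise ConvergenceError(
            f"{failures}/{reps} bootstrap replicates failed to converge"
        )
    ors = np.asarray(ors)
    alpha = (1 - level) / 2
    lo, med, hi = np.quantile(ors, [alpha, 0.5, 1 - alpha])
    return ORResult(float(med), float(lo), float(hi), level,
                    f"bootstrap-percentile({len(ors)} reps, {failures} dropped)")
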