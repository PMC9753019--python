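"""Synthetic individual-patient data with the structure the MAIC analysis assumes.

The real current-trial IPD is not public, so this module generates
patient tables whose covariate distribution matches the published arm
summaries: age approximately Normal (truncated at the trial's adult
eligibility bound of 18 years), sex and comorbidity Bernoulli, and a
binary 28-day death outcome from a logistic model whose intercept is
calibrated so the marginal death rate hits a target (e.g. 25/106).  The
default configuration reproduces the published high-dose arm moments
(age 66.1 +/- 10.7 years, 80.4% male, 70.1% with comorbidities).

Covariates are independent by default (no correlation structure is
published); an optional Gaussian-copula age-comorbidity correlation is
available for sensitivity studies.  The outcome coefficients are
synthetic, implementer-chosen plausible magnitudes - they are NOT
estimates from any trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .conjugate import BinomialSummary

__all__ = [
    "IPDGeneratorConfig",
    "generate_ipd",
    "calibrate_intercept",
    "reconstruct_binary_arm",
]

AGE_TRUNCATION = 18.0  # adult-eligibility lower bound, years


@dataclass(frozen=True)
class IPDGeneratorConfig:
    """Covariate moments, outcome model and calibration target for one arm.

    ``outcome_coefs`` are log-odds effects (per year of age, for male sex,
    for comorbidity); the intercept is solved so the marginal event rate
    equals ``target_marginal_rate`` under the covariate distribution.
    """

    n: int = 106
    age_mean: float = 66.1
    age_sd: float = 10.7
    p_male: float = 0.804
    p_comorb: float = 0.701
    outcome_coefs: dict = field(
        default_factory=lambda: {"age": 0.05, "male": 0.3, "comorbidity": 0.5}
    )
    target_marginal_rate: float = 25 / 106
    age_comorb_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not self.age_sd > 0:
            raise ValueError(f"age_sd must be positive, got {self.age_sd}")
        for name in ("p_male", "p_comorb", "target_marginal_rate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not -1 < self.age_comorb_corr < 1:
            raise ValueError("age_comorb_corr must lie in (-1, 1)")


def _truncnorm(cfg: IPDGeneratorConfig):
    a = (AGE_TRUNCATION - cfg.age_mean) / cfg.age_sd
    return stats.truncnorm(a, np.inf, loc=cfg.age_mean, scale=cfg.age_sd)


def _draw_covariates(cfg: IPDGeneratorConfig, n: int, rng: np.random.Generator):
    rho = cfg.age_comorb_corr
    if rho == 0.0:
        age = _truncnorm(cfg).rvs(size=n, random_state=rng)
        comorb = (rng.random(n) < cfg.p_comorb).astype(int)
    else:
        # Gaussian copula linking age and comorbidity
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        age = _truncnorm(cfg).ppf(stats.norm.cdf(z[:, 0]))
        # comorbidity indicator increasing in the latent normal, so a positive
        # rho yields a positive age-comorbidity association
        comorb = (stats.norm.cdf(z[:, 1]) > 1 - cfg.p_comorb).astype(int)
    male = (rng.random(n) < cfg.p_male).astype(int)
    return age, male, comorb


def _linear_predictor(cfg, age, male, comorb):
    c = cfg.outcome_coefs
    return (c.get("age", 0.0) * age + c.get("male", 0.0) * male
            + c.get("comorbidity", 0.0) * comorb)


def calibrate_intercept(
    cfg: IPDGeneratorConfig, n_mc: int = 200_000, tol: float = 1e-10
) -> float:
    """Intercept making the marginal event rate equal the configured target.

    Solves ``E[expit(c + x' coefs)] = target`` by bracketed root finding on
    a large Monte-Carlo draw of the covariate distribution (internal seed
    derived from the config seed, distinct from the sampling stream).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    age, male, comorb = _draw_covariates(cfg, n_mc, rng)
    eta = _linear_predictor(cfg, age, male, comorb)

    def achieved(c):
        return float(np.mean(special.expit(c + eta))) - cfg.target_marginal_rate

    lo, hi = -50.0, 50.0
    if achieved(lo) > 0 or achieved(hi) < 0:
        raise ValueError(
            f"target rate {cfg.target_marginal_rate} unreachable; achieved range "
            f"[{achieved(lo) + cfg.target_marginal_rate:.4f}, "
            f"{achieved(hi) + cfg.target_marginal_rate:.4f}]"
        )
    return float(optimize.brentq(achieved, lo, hi, xtol=tol))


def generate_ipd(cfg: IPDGeneratorConfig) -> pd.DataFrame:
    """One synthetic arm: columns ``age, male, comorbidity, death28``.

    Reproducible: the same config (including seed) yields an identical
    table.
    """
    intercept = calibrate_intercept(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xDA7A]))
    age, male, comorb = _draw_covariates(cfg, cfg.n, rng)
    p = special.expit(intercept + _linear_predictor(cfg, age, male, comorb))
    death = (rng.random(cfg.n) < p).astype(int)
    return pd.DataFrame(
        {"age": age, "male": male, "comorbidity": comorb, "death28": death}
    )


def reconstruct_binary_arm(summary: BinomialSummary) -> pd.DataFrame:
    """Outcome-only patient rows implied by an aggregate binomial summary:
    ``deaths`` ones followed by ``n - deaths`` zeros."""
    return pd.DataFrame(
        {"death28": np.concatenate(
            [np.ones(summary.deaths, dtype=int), np.zeros(summary.survivors, dtype=int)]
        )}
    )
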