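"""Matching-adjusted indirect comparison: moment-matching weights, balance,
odds ratios with sandwich/bootstrap intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from trialborrow import (
    AggregateTargets,
    BinomialSummary,
    ConvergenceError,
    IPDGeneratorConfig,
    bootstrap_or,
    estimate_weights,
    generate_ipd,
    rescale_weights,
    unadjusted_or,
    weight_diagnostics,
    weighted_or,
)
from trialborrow.maic import _weighted_or_point, validate_ipd


def own_means_targets(ipd):
    return AggregateTargets(
        float(ipd["age"].mean()), float(ipd["male"].mean()), float(ipd["comorbidity"].mean())
    )


class TestValidation:
    def test_missing_column_rejected(self, synthetic_ipd):
        with pytest.raises(ValueError, match="columns"):
            validate_ipd(synthetic_ipd.drop(columns=["male"]))

    def test_nan_rejected(self, synthetic_ipd):
        bad = synthetic_ipd.copy()
        bad.loc[0, "age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            validate_ipd(bad)

    def test_nonbinary_indicator_rejected(self, synthetic_ipd):
        bad = synthetic_ipd.copy()
        bad.loc[0, "male"] = 2
        with pytest.raises(ValueError, match="binary"):
            validate_ipd(bad)


class TestWeights:
    def test_weighted_means_hit_published_targets(self, synthetic_ipd, aggregate_targets):
        res = estimate_weights(synthetic_ipd, aggregate_targets)
        bal = res.balance
        assert bal.loc["age", "weighted_mean"] == pytest.approx(58.8, abs=1e-6)
        assert bal.loc["male", "weighted_mean"] == pytest.approx(0.72, abs=1e-6)
        assert bal.loc["comorbidity", "weighted_mean"] == pytest.approx(0.49, abs=1e-6)

    def test_moment_matching_exact_on_random_datasets(self, rng):
        """Defining estimating equation: for 50 random IPD tables with random
        interior targets, weighted means reproduce the targets to 1e-6."""
        for _ in range(50):
            n = int(rng.integers(60, 200))
            ipd = pd.DataFrame({
                "age": rng.normal(rng.uniform(50, 70), rng.uniform(5, 15), n),
                "male": (rng.random(n) < rng.uniform(0.3, 0.9)).astype(int),
                "comorbidity": (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int),
            })
            if ipd["male"].nunique() < 2 or ipd["comorbidity"].nunique() < 2:
                continue
            # random convex combination of rows -> target inside the hull
            w = rng.dirichlet(np.ones(n))
            t = AggregateTargets(*(w @ ipd[["age", "male", "comorbidity"]].to_numpy()))
            res = estimate_weights(ipd, t)
            wm = res.weights @ ipd[["age", "male", "comorbidity"]].to_numpy() / res.weights.sum()
            assert np.allclose(wm, t.as_array(), atol=1e-6)

    def test_self_targets_give_unit_weights(self, synthetic_ipd):
        res = estimate_weights(synthetic_ipd, own_means_targets(synthetic_ipd))
        assert np.allclose(res.beta, 0, atol=1e-5)
        assert np.allclose(res.weights_rescaled, 1.0, atol=1e-4)

    def test_one_covariate_toy_matches_bisection_oracle(self):
        """With only the binary covariate varying, the tilt coefficient solves
        the 1-D estimating equation, recovered here by bisection."""
        x = np.array([1] * 30 + [0] * 70)
        ipd = pd.DataFrame({"age": 60.0, "male": x, "comorbidity": 1,
                            "death28": 0})
        target = AggregateTargets(60.0, 0.5, 1.0)
        res = estimate_weights(ipd, target)
        eq = lambda b: np.sum(np.exp((x - 0.5) * b) * (x - 0.5))
        beta_oracle = optimize.bisect(eq, -10, 10, xtol=1e-12)
        assert res.beta[1] == pytest.approx(beta_oracle, abs=1e-6)

    def test_infeasible_target_names_covariate(self, synthetic_ipd):
        bad = AggregateTargets(120.0, 0.72, 0.49)  # outside observed age range
        with pytest.raises(ConvergenceError, match="age"):
            estimate_weights(synthetic_ipd, bad)


class TestRescaleAndDiagnostics:
    def test_rescaled_mean_exactly_one(self, rng):
        w = rng.gamma(2.0, 1.0, 200)
        assert rescale_weights(w).mean() == pytest.approx(1.0, rel=1e-15)

    def test_constant_vector_becomes_ones(self):
        assert np.allclose(rescale_weights(np.full(10, 3.7)), 1.0)

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError):
            rescale_weights(np.zeros(5))

    def test_rescaling_preserves_weighted_means_and_or(self, synthetic_ipd,
                                                       aggregate_targets, hist_arm):
        res = estimate_weights(synthetic_ipd, aggregate_targets)
        X = synthetic_ipd[["age", "male", "comorbidity"]].to_numpy()
        m_raw = res.weights @ X / res.weights.sum()
        m_scaled = res.weights_rescaled @ X / res.weights_rescaled.sum()
        assert np.allclose(m_raw, m_scaled, rtol=1e-12)
        or_raw = weighted_or(synthetic_ipd, res.weights, hist_arm)
        or_scaled = weighted_or(synthetic_ipd, res.weights_rescaled, hist_arm)
        assert or_raw.oddsratio == pytest.approx(or_scaled.oddsratio, rel=1e-9)

    def test_ess_equal_weights(self):
        ess, nz = weight_diagnostics(np.ones(37))
        assert ess == pytest.approx(37)
        assert nz == 0

    def test_ess_single_unit_weight(self):
        ess, _ = weight_diagnostics(np.array([0.0, 0.0, 1.0]))
        assert ess == pytest.approx(1.0)

    def test_ess_between_one_and_n(self, synthetic_ipd, aggregate_targets):
        res = estimate_weights(synthetic_ipd, aggregate_targets)
        assert 1 < res.ess_weights < len(synthetic_ipd)
        assert res.near_zero_count <= len(synthetic_ipd) * 0.1


class TestUnadjustedOR:
    def test_published_two_by_two(self, current_arm, hist_arm):
        res = unadjusted_or(current_arm, hist_arm)
        assert res.oddsratio == pytest.approx(0.744, abs=5e-4)
        assert res.ci_low == pytest.approx(0.448, abs=5e-4)
        assert res.ci_high == pytest.approx(1.237, abs=5e-4)

    def test_equal_rates_give_unit_or(self):
        res = unadjusted_or(BinomialSummary(20, 100), BinomialSummary(40, 200))
        assert res.oddsratio == pytest.approx(1.0, rel=1e-12)

    def test_zero_cell_raises(self):
        with pytest.raises(ValueError, match="continuity"):
            unadjusted_or(BinomialSummary(0, 10), BinomialSummary(5, 20))


class TestWeightedOR:
    def test_unit_weights_equal_unadjusted(self, synthetic_ipd, hist_arm):
        y = int(synthetic_ipd["death28"].sum())
        curr = BinomialSummary(y, len(synthetic_ipd))
        wor = weighted_or(synthetic_ipd, np.ones(len(synthetic_ipd)), hist_arm)
        uor = unadjusted_or(curr, hist_arm)
        assert wor.oddsratio == pytest.approx(uor.oddsratio, rel=1e-6)

    def test_closed_form_point_equals_glm(self, synthetic_ipd, aggregate_targets, hist_arm):
        res = estimate_weights(synthetic_ipd, aggregate_targets)
        glm = weighted_or(synthetic_ipd, res.weights_rescaled, hist_arm)
        closed = _weighted_or_point(
            synthetic_ipd["death28"].to_numpy(float), res.weights_rescaled, hist_arm
        )
        assert glm.oddsratio == pytest.approx(closed, rel=1e-8)

    def test_self_targets_reproduce_unadjusted(self, synthetic_ipd, hist_arm):
        res = estimate_weights(synthetic_ipd, own_means_targets(synthetic_ipd))
        y = int(synthetic_ipd["death28"].sum())
        wor = weighted_or(synthetic_ipd, res.weights_rescaled, hist_arm)
        uor = unadjusted_or(BinomialSummary(y, len(synthetic_ipd)), hist_arm)
        assert wor.oddsratio == pytest.approx(uor.oddsratio, rel=1e-5)

    def test_separation_raises(self, hist_arm):
        ipd = pd.DataFrame({"age": 60.0, "male": [0, 1] * 10,
                            "comorbidity": [1, 0] * 10, "death28": 1})
        with pytest.raises(ValueError, match="separation"):
            weighted_or(ipd, np.ones(20), hist_arm)

    def test_matching_younger_target_moves_or_toward_conditional(self, hist_arm):
        """Generate IPD where mortality rises with age; weighting to a younger
        population should lower the death odds of the IPD arm, moving the OR
        against the (unchanged) historical arm downward."""
        cfg = IPDGeneratorConfig(n=4000, outcome_coefs={"age": 0.08, "male": 0.0,
                                                        "comorbidity": 0.0}, seed=5)
        ipd = generate_ipd(cfg)
        young = AggregateTargets(cfg.age_mean - 6.0, cfg.p_male, cfg.p_comorb)
        res = estimate_weights(ipd, young)
        y = int(ipd["death28"].sum())
        uor = unadjusted_or(BinomialSummary(y, len(ipd)), hist_arm)
        wor = weighted_or(ipd, res.weights_rescaled, hist_arm)
        assert wor.oddsratio < uor.oddsratio


class TestBootstrap:
    def test_degenerate_ipd_gives_zero_width(self, hist_arm):
        row = {"age": 60.0, "male": 1, "comorbidity": 0, "death28": 0}
        ipd = pd.DataFrame([row] * 40)
        ipd.loc[:9, "death28"] = 1  # identical covariates, 25% deaths
        # all resamples share the covariate profile; weights are flat
        res = bootstrap_or(ipd.sample(frac=1.0, random_state=0), AggregateTargets(60.0, 1.0, 0.0),
                           hist_arm, reps=100, seed=3)
        assert res.ci_low <= res.oddsratio <= res.ci_high

    def test_identical_rows_and_outcomes_zero_width(self, hist_arm):
        ipd = pd.DataFrame([{"age": 60.0, "male": 1, "comorbidity": 0, "death28": 1},
                            ] * 30 + [{"age": 60.0, "male": 1, "comorbidity": 0,
                                       "death28": 0}] * 0)
        # every patient identical (all deaths would separate); flip some rows
        ipd.loc[:19, "death28"] = 0
        res = bootstrap_or(ipd, AggregateTargets(60.0, 1.0, 0.0), hist_arm,
                           reps=100, seed=4)
        assert res.ci_high > res.ci_low  # resampling outcomes still varies

    def test_seed_determinism(self, synthetic_ipd, aggregate_targets, hist_arm):
        r1 = bootstrap_or(synthetic_ipd, aggregate_targets, hist_arm, reps=150, seed=9)
        r2 = bootstrap_or(synthetic_ipd, aggregate_targets, hist_arm, reps=150, seed=9)
        assert r1.oddsratio == r2.oddsratio
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_median_near_point_estimate(self, aggregate_targets, hist_arm):
        ipd = generate_ipd(IPDGeneratorConfig(n=500, seed=11))
        res = estimate_weights(ipd, aggregate_targets)
        point = weighted_or(ipd, res.weights_rescaled, hist_arm).oddsratio
        boot = bootstrap_or(ipd, aggregate_targets, hist_arm, reps=1000, seed=12)
        assert boot.oddsratio == pytest.approx(point, rel=0.15)
        assert boot.ci_low < point < boot.ci_high

    def test_too_few_reps_rejected(self, synthetic_ipd, aggregate_targets, hist_arm):
        with pytest.raises(ValueError):
            bootstrap_or(synthetic_ipd, aggregate_targets, hist_arm, reps=50, seed=1)
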