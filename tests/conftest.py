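import numpy as np
import pytest

from trialborrow import (
    AggregateTargets,
    BetaParams,
    BinomialSummary,
    IPDGeneratorConfig,
    generate_ipd,
)

# the two published dexamethasone arms used throughout:
# current trial 25 deaths / 106 patients, historical 95 / 324
CURRENT = BinomialSummary(25, 106)
HISTORICAL = BinomialSummary(95, 324)


@pytest.fixture(scope="session")
def current_arm():
    return CURRENT


@pytest.fixture(scope="session")
def hist_arm():
    return HISTORICAL


@pytest.fixture(scope="session")
def flat_prior():
    return BetaParams(1.0, 1.0)


@pytest.fixture(scope="session")
def aggregate_targets():
    """Published comparator-arm covariate means (age years, proportions)."""
    return AggregateTargets(age_mean=58.8, male_prop=0.72, comorbidity_prop=0.49)


@pytest.fixture(scope="session")
def synthetic_ipd():
    """Default synthetic current-arm IPD (106 patients, published moments)."""
    return generate_ipd(IPDGeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def large_synthetic_ipd():
    return generate_ipd(IPDGeneratorConfig(n=10_000, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
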