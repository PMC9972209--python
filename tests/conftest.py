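import pytest

from sepsopt import (
    ExcessCostTable,
    GeneratorConfig,
    aggregate_mdc,
    generate_claims,
    match_controls,
    sweep,
)


@pytest.fixture(scope="session")
def cohort_claims():
    """Full-scale synthetic cohort (131 DRGs, ~20k encounters)."""
    return generate_claims(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_pairs(cohort_claims):
    result = match_controls(cohort_claims)
    assert not len(result.unmatched)
    return result.pairs


@pytest.fixture(scope="session")
def site_table(cohort_claims, cohort_pairs):
    """Per-MDC excess cost table estimated from the synthetic cohort."""
    return aggregate_mdc(cohort_pairs, cohort_claims)


@pytest.fixture(scope="session")
def default_sweep(site_table):
    """One full default-grid sweep shared by the policy-comparison tests."""
    return sweep(site_table)


@pytest.fixture
def one_mdc_table():
    """Single category: missed-case cost $1,000, 10 septic, 100 controls."""
    return ExcessCostTable.from_records([("MDC_A", 1000.0, 10, 100)])
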