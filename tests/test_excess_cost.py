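"""Matching estimator: tie-breaks, brute-force oracle, aggregation, scaling."""

import numpy as np
import pandas as pd
import pytest

from sepsopt import (
    ConfigurationError,
    ExcessCostTable,
    GeneratorConfig,
    ScalingFactors,
    aggregate_mdc,
    generate_claims,
    match_controls,
    scale_national,
    summarize_drg,
)
from sepsopt.synthetic_claims import DEFAULT_TRUE_EXCESS_BY_MDC, default_drg_codes


def claims_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "encounter_id",
            "drg_code",
            "drg_weight",
            "mdc",
            "charlson",
            "payment",
            "sepsis_flag",
        ],
    )


def test_nearest_charlson_control_is_chosen():
    claims = claims_frame(
        [
            ("S1", "190", 1.2, "RESP", 4, 30_000.0, True),
            ("C1", "190", 1.2, "RESP", 1, 12_000.0, False),
            ("C2", "190", 1.2, "RESP", 5, 14_000.0, False),
        ]
    )
    pairs = match_controls(claims).pairs
    assert pairs.iloc[0]["control_id"] == "C2"  # |5-4| < |1-4|
    assert pairs.iloc[0]["excess"] == 16_000.0


def test_charlson_tie_broken_by_control_id():
    # C1 and C2 are equally distant in comorbidity; the lexicographically
    # smallest control id wins, making the match order-independent.
    claims = claims_frame(
        [
            ("S1", "190", 1.2, "RESP", 4, 30_000.0, True),
            ("C1", "190", 1.2, "RESP", 3, 12_000.0, False),
            ("C2", "190", 1.2, "RESP", 5, 14_000.0, False),
        ]
    )
    pairs = match_controls(claims).pairs
    assert pairs.iloc[0]["control_id"] == "C1"
    assert pairs.iloc[0]["excess"] == 18_000.0


def test_identical_control_gives_zero_excess():
    claims = claims_frame(
        [
            ("S1", "100", 1.0, "A", 2, 9_000.0, True),
            ("C1", "100", 1.0, "A", 2, 9_000.0, False),
        ]
    )
    assert match_controls(claims).pairs.iloc[0]["excess"] == 0.0


def test_empty_stratum_reported_unmatched_not_fatal():
    claims = claims_frame(
        [
            ("S1", "100", 1.0, "A", 2, 9_000.0, True),
            ("C1", "100", 1.0, "A", 2, 7_000.0, False),
            ("S2", "200", 2.0, "B", 1, 20_000.0, True),  # no controls in 200
        ]
    )
    result = match_controls(claims)
    assert len(result.pairs) == 1
    assert list(result.unmatched["encounter_id"]) == ["S2"]


def test_matching_equals_bruteforce_enumeration():
    """Every pair must agree with exhaustive search of its stratum."""
    cfg = GeneratorConfig(
        n_drgs=6, n_controls_per_drg=15, n_septic_per_drg=3, outlier_tail=0.6, seed=5
    )
    claims = generate_claims(cfg)
    pairs = match_controls(claims).pairs.set_index("septic_id")
    for _, row in claims[claims.sepsis_flag].iterrows():
        stratum = claims[
            (~claims.sepsis_flag)
            & (claims.drg_code == row.drg_code)
            & (claims.drg_weight == row.drg_weight)
        ]
        best = min(
            stratum.itertuples(index=False),
            key=lambda c: (abs(c.charlson - row.charlson), c.encounter_id),
        )
        assert pairs.loc[row.encounter_id, "control_id"] == best.encounter_id
        assert pairs.loc[row.encounter_id, "excess"] == pytest.approx(
            row.payment - best.payment
        )


@pytest.mark.parametrize("shuffle_seed", [0, 1, 2])
def test_matching_invariant_under_row_permutation(shuffle_seed):
    cfg = GeneratorConfig(
        n_drgs=5, n_controls_per_drg=10, n_septic_per_drg=2, outlier_tail=0.5, seed=3
    )
    claims = generate_claims(cfg)
    shuffled = claims.sample(frac=1, random_state=shuffle_seed).reset_index(drop=True)
    a = match_controls(claims).pairs.sort_values("septic_id").reset_index(drop=True)
    b = match_controls(shuffled).pairs.sort_values("septic_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_matching_is_with_replacement():
    # two sepsis cases compete for the single best control: both get it
    claims = claims_frame(
        [
            ("S1", "100", 1.0, "A", 3, 20_000.0, True),
            ("S2", "100", 1.0, "A", 3, 25_000.0, True),
            ("C1", "100", 1.0, "A", 3, 10_000.0, False),
            ("C2", "100", 1.0, "A", 9, 11_000.0, False),
        ]
    )
    pairs = match_controls(claims).pairs
    assert list(pairs["control_id"]) == ["C1", "C1"]


def test_summarize_drg_arithmetic():
    pairs = pd.DataFrame(
        {
            "septic_id": ["a", "b", "c", "d"],
            "control_id": ["x", "y", "z", "w"],
            "drg_code": ["100", "100", "100", "200"],
            "drg_weight": [1.0, 1.0, 1.0, 2.0],
            "excess": [-1_000.0, 3_000.0, 10_000.0, 500.0],
        }
    )
    out = summarize_drg(pairs).set_index("drg_code")
    assert out.loc["100", "mean_excess"] == 4_000.0
    assert out.loc["100", "median_excess"] == 3_000.0
    assert out.loc["100", "n_pairs"] == 3
    assert out.loc["200", "mean_excess"] == out.loc["200", "median_excess"] == 500.0
    assert len(summarize_drg(pairs.iloc[0:0])) == 0


def test_aggregate_mdc_is_unweighted_mean_of_drg_means():
    claims = claims_frame(
        [
            ("S1", "100", 1.0, "A", 0, 3_000.0, True),
            ("C1", "100", 1.0, "A", 0, 1_000.0, False),
            ("S2", "200", 1.0, "A", 0, 7_000.0, True),
            ("S3", "200", 1.0, "A", 0, 7_000.0, True),
            ("C2", "200", 1.0, "A", 0, 1_000.0, False),
        ]
    )
    pairs = match_controls(claims).pairs
    # DRG means: 2000 and 6000 → drg_mean 4000; pair-weighted (2000+6000+6000)/3
    assert aggregate_mdc(pairs, claims).data.iloc[0]["cost_fn"] == 4_000.0
    pw = aggregate_mdc(pairs, claims, weighting="pair_weighted")
    assert pw.data.iloc[0]["cost_fn"] == pytest.approx(14_000.0 / 3)


def test_aggregate_counts_are_mdc_encounter_counts(cohort_claims, cohort_pairs):
    table = aggregate_mdc(cohort_pairs, cohort_claims)
    counts = cohort_claims.groupby("mdc")["sepsis_flag"].agg(["sum", "size"])
    for row in table.data.itertuples(index=False):
        assert row.n_septic == counts.loc[row.mdc, "sum"]
        assert row.n_controls == counts.loc[row.mdc, "size"] - counts.loc[row.mdc, "sum"]


def test_zero_noise_recovers_injected_excess_exactly():
    cfg = GeneratorConfig(
        n_drgs=32, n_controls_per_drg=20, n_septic_per_drg=2, outlier_tail=0.0, seed=9
    )
    claims = generate_claims(cfg)
    table = aggregate_mdc(match_controls(claims).pairs, claims)
    for row in table.data.itertuples(index=False):
        assert row.cost_fn == pytest.approx(
            DEFAULT_TRUE_EXCESS_BY_MDC[row.mdc], abs=1e-6
        )


def test_pair_excess_is_payment_subtraction(cohort_claims, cohort_pairs):
    payments = cohort_claims.set_index("encounter_id")["payment"]
    recomputed = (
        payments.loc[cohort_pairs["septic_id"]].to_numpy()
        - payments.loc[cohort_pairs["control_id"]].to_numpy()
    )
    np.testing.assert_allclose(cohort_pairs["excess"].to_numpy(), recomputed)


def test_scale_national_arithmetic():
    table = ExcessCostTable.from_records([("A", 10_000.0, 4, 100)])
    out = scale_national(
        table, ScalingFactors(payment_ratio={"A": 1.5}, site_share=0.002)
    )
    assert out.scope == "national"
    assert out.data.iloc[0]["cost_fn"] == 15_000.0
    assert out.data.iloc[0]["n_septic"] == 2_000.0
    assert out.total_excess == 15_000.0 * 2_000.0


def test_scale_identity_factors_only_flip_scope():
    table = ExcessCostTable.from_records([("A", 10_000.0, 4, 100), ("B", -2_000.0, 1, 5)])
    out = scale_national(
        table, ScalingFactors(payment_ratio={"A": 1.0, "B": 1.0}, site_share=1.0)
    )
    assert out.scope == "national"
    pd.testing.assert_frame_equal(
        out.data.astype(float, errors="ignore").reset_index(drop=True),
        table.data.astype(float, errors="ignore").reset_index(drop=True),
        check_dtype=False,
    )


def test_scale_drg_level_ratios_aggregate_by_mdc():
    table = ExcessCostTable.from_records([("A", 1_000.0, 2, 10)])
    factors = ScalingFactors(
        payment_ratio={"100": 1.0, "200": 3.0}, site_share=0.5, level="drg"
    )
    out = scale_national(table, factors, drg_to_mdc={"100": "A", "200": "A"})
    assert out.data.iloc[0]["cost_fn"] == 2_000.0  # mean ratio 2.0


def test_total_national_excess_is_sum_of_products(site_table):
    factors = ScalingFactors(
        payment_ratio={m: 1.5 for m in site_table.mdcs}, site_share=0.004
    )
    out = scale_national(site_table, factors)
    expected = sum(
        1.5 * row.cost_fn * (row.n_septic / 0.004)
        for row in site_table.data.itertuples(index=False)
    )
    assert out.total_excess == pytest.approx(expected, rel=1e-12)


def test_scale_rejects_bad_share_and_non_site_tables(site_table):
    with pytest.raises(ConfigurationError, match="site_share"):
        ScalingFactors(payment_ratio={"A": 1.0}, site_share=0.0)
    national = scale_national(
        site_table,
        ScalingFactors(payment_ratio={m: 1.0 for m in site_table.mdcs}, site_share=1.0),
    )
    with pytest.raises(ValueError, match="site-scope"):
        scale_national(national, ScalingFactors(payment_ratio={}, site_share=1.0))


def test_aggregate_rejects_unmapped_drg():
    claims = claims_frame(
        [
            ("S1", "100", 1.0, "A", 0, 3_000.0, True),
            ("C1", "100", 1.0, "A", 0, 1_000.0, False),
        ]
    )
    pairs = match_controls(claims).pairs
    alien = pairs.copy()
    alien["drg_code"] = "999"
    with pytest.raises(ValueError, match="999"):
        aggregate_mdc(alien, claims)


def test_excess_table_csv_roundtrip(tmp_path, site_table):
    path = tmp_path / "costs.csv"
    site_table.to_csv(path)
    back = ExcessCostTable.from_csv(path)
    assert back.scope == site_table.scope
    pd.testing.assert_frame_equal(back.data, site_table.data, check_dtype=False)
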