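"""Incremental-payment arithmetic, summaries, annualization, sensitivity."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracturecost import (
    GeneratorConfig,
    IncrementalCostModel,
    annualize,
    build_cohort,
    incremental_payments,
    round_half_away,
    sensitivity_exclude_deaths,
    simulate_population,
    summarize,
    yen_to_usd,
)
from fracturecost.estimator import DELTA_COLUMNS


def _cohort(rows):
    cols = [
        "person_id",
        "sex",
        "age_band",
        "prefecture",
        "index_month",
        "admission_date",
        "site",
        "procedure_class",
        "died_within_6m",
        "cci_score",
    ]
    return pd.DataFrame(rows, columns=cols)


def _pay(rows):
    return pd.DataFrame(rows, columns=["person_id", "month", "category", "amount_yen"])


ONE = _cohort([("A", "male", "80-84", 5, "2015-01", "2015-01-05", "neck", "orif", False, 0)])


def test_toy_ledger_post_minus_pre():
    # pre: 10,000/month x 6; post: 550,000 then 10,000 x 5 -> 600,000 - 60,000
    rows = [("A", m, "inpatient", 10_000) for m in
            ("2014-07", "2014-08", "2014-09", "2014-10", "2014-11", "2014-12")]
    rows += [("A", "2015-01", "inpatient", 550_000)]
    rows += [("A", m, "inpatient", 10_000) for m in
             ("2015-02", "2015-03", "2015-04", "2015-05", "2015-06")]
    inc = incremental_payments(ONE, _pay(rows))
    assert int(inc["delta_total_yen"].iloc[0]) == 540_000
    assert int(inc["delta_inpatient_yen"].iloc[0]) == 540_000


def test_all_zero_months_give_zero_deltas():
    inc = incremental_payments(ONE, _pay([]))
    assert (inc[list(DELTA_COLUMNS.values()) + ["delta_total_yen"]] == 0).all().all()


def test_window_boundaries_and_excluded_other():
    rows = [
        ("A", "2014-06", "inpatient", 999),          # 7 months pre: outside
        ("A", "2014-07", "inpatient", 1_000),        # index-6: inside pre
        ("A", "2014-12", "inpatient", 2_000),        # index-1: inside pre
        ("A", "2015-01", "inpatient", 50_000),       # index: inside post
        ("A", "2015-06", "inpatient", 7_000),        # index+5: inside post
        ("A", "2015-07", "inpatient", 888),          # index+6: outside
        ("A", "2015-02", "excluded_other", 123_456), # never counted
    ]
    inc = incremental_payments(ONE, _pay(rows))
    assert int(inc["delta_total_yen"].iloc[0]) == 50_000 + 7_000 - 1_000 - 2_000


def test_death_truncated_months_contribute_zero_not_imputed():
    cohort = _cohort(
        [("A", "male", "80-84", 5, "2015-01", "2015-01-05", "neck", "orif", True, 0)]
    )
    rows = [("A", "2015-01", "inpatient", 900_000), ("A", "2015-02", "inpatient", 100_000)]
    inc = incremental_payments(cohort, _pay(rows))
    assert int(inc["delta_total_yen"].iloc[0]) == 1_000_000


def test_delta_total_is_sum_of_category_deltas(small_sim, small_cohort):
    _, bundle, _ = small_sim
    cohort, _ = small_cohort
    inc = incremental_payments(cohort, bundle.payments)
    parts = sum(inc[c] for c in DELTA_COLUMNS.values())
    assert (inc["delta_total_yen"] == parts).all()


def test_summarize_single_person_and_even_median():
    inc = incremental_payments(ONE, _pay([("A", "2015-01", "inpatient", 2_000_000)]))
    s = summarize(inc, ONE)
    assert s["n"].iloc[0] == 1
    assert s["mean_total_yen"].iloc[0] == s["median_total_yen"].iloc[0] == 2_000_000

    cohort = _cohort(
        [(p, "male", "80-84", 5, "2015-01", "2015-01-05", "neck", "orif", False, 0)
         for p in "ABCD"]
    )
    inc = pd.DataFrame(
        {
            "person_id": list("ABCD"),
            "delta_inpatient_yen": [1, 2, 3, 4],
            "delta_outpatient_facility_yen": [0] * 4,
            "delta_outpatient_pharmacy_yen": [0] * 4,
            "delta_total_yen": [1, 2, 3, 4],
        }
    )
    s = summarize(inc, cohort)
    assert s["mean_total_yen"].iloc[0] == 2.5
    assert s["median_total_yen"].iloc[0] == 2.5


def test_published_sex_means_pool_to_overall_mean():
    # sex-specific means and counts recombine to the printed pooled mean
    total = Fraction(2_550_000) * 28_868 + Fraction(2_494_000) * 113_493
    pooled = total / (28_868 + 113_493)
    assert round_half_away(pooled, 1000) == 2_505_000


def test_stratified_means_recompose_overall_exactly(small_sim, small_cohort):
    _, bundle, _ = small_sim
    cohort, _ = small_cohort
    inc = incremental_payments(cohort, bundle.payments)
    overall = summarize(inc, cohort)
    for by in ("sex", "age_band", "site", "procedure_class", "prefecture"):
        s = summarize(inc, cohort, by=by)
        strata = s[s[by] != "overall"]
        assert strata["n"].sum() == len(cohort)
        assert strata["sum_total_yen"].sum() == overall["sum_total_yen"].iloc[0]


def test_unmatched_increment_rejected():
    inc = incremental_payments(ONE, _pay([]))
    with pytest.raises(ValueError, match="cohort"):
        summarize(inc, ONE[ONE["person_id"] != "A"])


def test_annualize_unit_case_and_national_scale():
    assert annualize(1, 13, 13) == 12
    assert annualize(1_000, 0, 13) == 0
    exact = annualize(2_550_000, 28_868, 13)
    assert round_half_away(exact) == 67_950_830_769


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    mean=st.integers(0, 10_000_000),
    n=st.integers(0, 200_000),
    k=st.integers(1, 9),
    window=st.integers(1, 24),
)
def test_annualize_is_linear_in_n_and_mean(mean, n, k, window):
    assert annualize(mean, k * n, window) == k * annualize(mean, n, window)
    assert annualize(k * mean, n, window) == k * annualize(mean, n, window)


def test_annualize_rejects_bad_window():
    with pytest.raises(ValueError):
        annualize(1_000, 10, 0)


@pytest.mark.parametrize(
    "yen,usd",
    [(2_550_000, 23_180), (2_369_000, 21_540), (2_444_000, 22_220), (0, 0), (-76_000, -690)],
)
def test_yen_to_usd_nearest_ten(yen, usd):
    assert yen_to_usd(yen) == usd


def test_yen_to_usd_rounding_unit_and_half_away():
    assert yen_to_usd(67_960_000_000, rounding_unit=10_000_000) == 620_000_000
    assert round_half_away(25, 10) == 30   # tie goes away from zero
    assert round_half_away(-25, 10) == -30


def test_sensitivity_identical_when_no_deaths():
    inc = incremental_payments(ONE, _pay([("A", "2015-01", "inpatient", 1_000)]))
    base = summarize(inc, ONE)
    sens = sensitivity_exclude_deaths(inc, ONE)
    pd.testing.assert_frame_equal(base, sens)


def test_sensitivity_of_all_deaths_is_empty_summary():
    cohort = _cohort(
        [("A", "male", "80-84", 5, "2015-01", "2015-01-05", "neck", "orif", True, 0)]
    )
    inc = incremental_payments(cohort, _pay([]))
    sens = sensitivity_exclude_deaths(inc, cohort)
    assert sens["n"].iloc[-1] == 0
    assert np.isnan(sens["mean_total_yen"].iloc[-1])


def test_death_truncation_biases_base_case_downward():
    # non-negative post effects + deaths: excluding decedents raises the mean
    cfg = GeneratorConfig(
        n_individuals=2500,
        seed=31,
        p_death_within6={"male": 0.1, "female": 0.1},
        fracture_cost_effect={
            "inpatient": [1_600_000, 600_000, 180_000, 90_000, 60_000, 40_000]
        },
    )
    bundle, _ = simulate_population(cfg)
    cohort, _ = build_cohort(bundle, cfg.index_window)
    res = IncrementalCostModel.from_bundle(cohort, bundle).fit()
    base = res.summarize()["mean_total_yen"].iloc[0]
    sens = res.sensitivity_exclude_deaths()["mean_total_yen"].iloc[0]
    assert cohort["died_within_6m"].any()
    assert sens >= base


def test_linear_background_trend_bias_matches_closed_form():
    # deterministic linear monthly cost a + b t: the pre/post difference is
    # exactly 36 b regardless of a or the index month
    b = 500
    months_all = [f"2014-{m:02d}" for m in range(4, 13)] + [
        f"2015-{m:02d}" for m in range(1, 13)
    ]
    rows = [
        ("A", m, "outpatient_facility", 10_000 + b * t)
        for t, m in enumerate(months_all)
    ]
    inc = incremental_payments(ONE, _pay(rows))
    assert int(inc["delta_total_yen"].iloc[0]) == 36 * b


def test_results_summary_prints_cases_and_total(small_sim, small_cohort):
    _, bundle, _ = small_sim
    cohort, _ = small_cohort
    res = IncrementalCostModel.from_bundle(cohort, bundle).fit()
    text = res.summary()
    assert f"cases: {len(cohort)}" in text
    assert "billion yen" in text
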