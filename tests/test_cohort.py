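"""Incident-case identification, eligibility rules, and oracle equivalence."""

import pandas as pd
import pytest

from fracturecost import (
    apply_eligibility,
    build_cohort,
    classify_procedure,
    classify_site,
    find_candidate_events,
    flag_death_within_6m,
)
from fracturecost.claims import TABLE_COLUMNS, normalize_bundle
from fracturecost.cohort import Candidate, ConsistencyError


def _bundle(individuals=(), payments=(), diseases=(), procedures=(), admissions=()):
    return normalize_bundle(
        individuals=pd.DataFrame(list(individuals), columns=TABLE_COLUMNS["individuals"]),
        payments=pd.DataFrame(list(payments), columns=TABLE_COLUMNS["payments"]),
        diseases=pd.DataFrame(list(diseases), columns=TABLE_COLUMNS["diseases"]),
        procedures=pd.DataFrame(list(procedures), columns=TABLE_COLUMNS["procedures"]),
        admissions=pd.DataFrame(list(admissions), columns=TABLE_COLUMNS["admissions"]),
    )


_PERSON = ("A", "female", "80-84", 5, "2014-04", "2016-03", "")


def test_candidate_requires_code_and_admission_in_same_month():
    bundle = _bundle(
        individuals=[_PERSON],
        diseases=[("A", "2015-01", "HIPFX-NECK-FRAG-A", 0)],
        admissions=[("A", "2015-01-10", "2015-02-01", 5)],
        procedures=[("A", "2015-01-11", "PROC-BHA-A")],
    )
    cands = find_candidate_events(bundle)
    assert len(cands) == 1
    assert cands[0].index_month == "2015-01"
    assert cands[0].admission_date == "2015-01-10"


def test_suspicious_only_fragility_code_yields_no_candidate():
    bundle = _bundle(
        individuals=[_PERSON],
        diseases=[("A", "2015-01", "HIPFX-NECK-FRAG-A", 1)],
        admissions=[("A", "2015-01-10", "2015-02-01", 5)],
    )
    assert find_candidate_events(bundle) == []


def test_earliest_qualifying_month_wins():
    bundle = _bundle(
        individuals=[_PERSON],
        diseases=[
            ("A", "2014-11", "HIPFX-EXTRACAP-FRAG-A", 0),
            ("A", "2015-06", "HIPFX-NECK-FRAG-A", 0),
        ],
        admissions=[
            ("A", "2014-11-03", "2014-12-01", 5),
            ("A", "2015-06-20", "2015-07-15", 5),
        ],
        procedures=[("A", "2014-11-04", "PROC-ORIF-A"), ("A", "2015-06-21", "PROC-BHA-A")],
    )
    cands = find_candidate_events(bundle)
    assert len(cands) == 1
    assert cands[0].index_month == "2014-11"


def test_code_outside_index_window_is_not_a_candidate():
    bundle = _bundle(
        individuals=[_PERSON],
        diseases=[("A", "2016-01", "HIPFX-NECK-FRAG-A", 0)],
        admissions=[("A", "2016-01-10", "2016-02-01", 5)],
    )
    assert find_candidate_events(bundle) == []


@pytest.mark.parametrize(
    "classes,expected",
    [
        ({"neck_fragility", "extracapsular_fragility"}, "neck"),
        ({"extracapsular_fragility"}, "extracapsular"),
        ({"neck_fragility"}, "neck"),
    ],
)
def test_site_priority_neck_over_extracapsular(classes, expected):
    assert classify_site(classes) == expected


def test_site_requires_a_fragility_code():
    with pytest.raises(ValueError):
        classify_site({"hip_other"})


@pytest.mark.parametrize(
    "classes,expected",
    [
        ({"bipolar", "orif"}, "bipolar"),
        ({"conservative"}, "conservative"),
        ({"thr", "bipolar", "orif", "conservative"}, "thr"),
        ({"orif", "conservative"}, "orif"),
    ],
)
def test_procedure_priority_thr_bipolar_orif_conservative(classes, expected):
    assert classify_procedure(classes) == expected


def test_procedure_requires_a_qualifying_record():
    with pytest.raises(ValueError):
        classify_procedure({"other"})


@pytest.mark.parametrize(
    "death,expected",
    [("2015-01", True), ("2015-06", True), ("2015-07", False), ("", False)],
)
def test_death_flag_covers_index_month_plus_five(death, expected):
    assert flag_death_within_6m(death, "2015-01") is expected


@pytest.mark.parametrize("day_offset,kept", [(14, True), (15, True), (16, False), (19, False)])
def test_surgery_day_convention_keeps_day_16_excludes_day_17(day_offset, kept):
    # admission day is day 1, so offset 15 = day 16 (kept), 16 = day 17 (excluded)
    proc_date = f"2015-01-{5 + day_offset:02d}"
    bundle = _bundle(
        individuals=[_PERSON],
        diseases=[("A", "2015-01", "HIPFX-NECK-FRAG-A", 0)],
        admissions=[("A", "2015-01-05", "2015-03-01", 5)],
        procedures=[("A", proc_date, "PROC-ORIF-A")],
    )
    cohort, excl = build_cohort(bundle)
    if kept:
        assert len(cohort) == 1
        assert cohort["procedure_class"].iloc[0] == "orif"
    else:
        assert len(cohort) == 0
        assert list(excl["reason"]) == ["late_surgery"]


def test_open_fracture_code_before_index_is_prior_fracture():
    bundle = _bundle(
        individuals=[_PERSON],
        diseases=[
            ("A", "2014-10", "HIPFX-OPEN-A", 0),
            ("A", "2015-01", "HIPFX-NECK-FRAG-A", 0),
        ],
        admissions=[("A", "2015-01-05", "2015-02-01", 5)],
        procedures=[("A", "2015-01-06", "PROC-BHA-A")],
    )
    cohort, excl = build_cohort(bundle)
    assert len(cohort) == 0
    assert list(excl["reason"]) == ["prior_fracture"]


def test_conservative_management_requires_no_surgery_and_explicit_code():
    bundle = _bundle(
        individuals=[_PERSON, ("B", "male", "75-79", 5, "2014-04", "2016-03", "")],
        diseases=[
            ("A", "2015-01", "HIPFX-EXTRACAP-FRAG-A", 0),
            ("B", "2015-01", "HIPFX-EXTRACAP-FRAG-A", 0),
        ],
        admissions=[
            ("A", "2015-01-05", "2015-02-01", 5),
            ("B", "2015-01-05", "2015-02-01", 5),
        ],
        procedures=[("A", "2015-01-06", "PROC-CONS-A")],
    )
    cohort, excl = build_cohort(bundle)
    assert list(cohort["person_id"]) == ["A"]
    assert cohort["procedure_class"].iloc[0] == "conservative"
    assert list(excl["person_id"]) == ["B"]
    assert list(excl["reason"]) == ["no_qualifying_procedure"]


def test_unknown_candidate_person_raises_consistency_error():
    bundle = _bundle(individuals=[_PERSON])
    ghost = Candidate("ZZZ", "2015-01", "2015-01-05", "2015-02-01", 5)
    with pytest.raises(ConsistencyError):
        apply_eligibility([ghost], bundle)


def test_filter_fixture_keeps_exactly_the_eligible_person(filter_fixture):
    bundle, truth = filter_fixture
    cohort, excl = build_cohort(bundle)
    assert len(cohort) == 1
    assert cohort["person_id"].iloc[0] == "F1"
    assert cohort["site"].iloc[0] == "neck"
    assert cohort["procedure_class"].iloc[0] == "bipolar"
    assert len(excl) == 5
    expected = truth.events.set_index("person_id")["exclusion_reason"]
    got = excl.set_index("person_id")["reason"]
    assert got.to_dict() == expected[expected != ""].to_dict()


def test_candidates_partition_into_cohort_and_exclusions(small_sim, small_cohort):
    cfg, bundle, _ = small_sim
    cohort, exclusions = small_cohort
    candidates = find_candidate_events(bundle, cfg.index_window)
    assert len(candidates) == len(cohort) + len(exclusions)
    ids = set(cohort["person_id"]) | set(exclusions["person_id"])
    assert ids == {c.person_id for c in candidates}
    assert set(cohort["person_id"]).isdisjoint(set(exclusions["person_id"]))


def test_cohort_matches_ground_truth_labels_exactly(small_sim, small_cohort):
    _, _, truth = small_sim
    cohort, exclusions = small_cohort
    elig = truth.eligible()
    assert set(cohort["person_id"]) == set(elig["person_id"])
    merged = cohort.merge(elig, on="person_id", suffixes=("", "_true"))
    assert (merged["site"] == merged["site_true"]).all()
    assert (merged["procedure_class"] == merged["procedure_class_true"]).all()
    assert (merged["died_within_6m"] == merged["died_within_6m_true"]).all()
    labelled = truth.events.set_index("person_id")["exclusion_reason"]
    for r in exclusions.itertuples():
        assert labelled.get(r.person_id, "") == r.reason


def test_no_cohort_member_has_prior_hip_code(small_sim, small_cohort):
    _, bundle, _ = small_sim
    cohort, _ = small_cohort
    hip = bundle.diseases[
        bundle.diseases["code_class"].isin(
            ("neck_fragility", "extracapsular_fragility", "hip_other")
        )
        & (bundle.diseases["suspicious"] == 0)
    ]
    idx = cohort.set_index("person_id")["index_month"]
    own = hip[hip["person_id"].isin(idx.index)]
    assert (own["month"] >= own["person_id"].map(idx)).all()


def test_site_and_procedure_counts_partition_cohort(small_cohort):
    cohort, _ = small_cohort
    assert cohort.groupby("site").size().sum() == len(cohort)
    assert cohort.groupby("procedure_class").size().sum() == len(cohort)
    assert set(cohort["site"]) <= {"neck", "extracapsular"}
    assert set(cohort["procedure_class"]) <= {"thr", "bipolar", "orif", "conservative"}
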