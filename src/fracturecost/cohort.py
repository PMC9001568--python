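"""Incident fragility hip-fracture identification and eligibility filtering.

A candidate index event is the earliest month inside the index window in
which a person has a non-suspicious fragility hip-fracture disease code
(femoral neck or extracapsular) co-occurring with a hospital admission in
the same month. Eligibility then requires, in order:

1. age band 60-64 or older at baseline;
2. washout — no non-suspicious hip disease code of any class (fragility,
   open, stress) in any observed month before the index month;
3. at least 6 enrolled months strictly before the index month;
4. a qualifying procedure (THR, bipolar hip arthroplasty, ORIF, or
   conservative management) linked to the index admission by date, with
   any surgery performed no later than day 16 of the admission (admission
   day = day 1; day >= 17 is excluded as a likely in-hospital fracture).

Persons dying within the admission month or the following five months are
retained and flagged; every candidate not retained receives exactly one
logged exclusion reason, so cohort plus exclusion log partition the
candidates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from . import months
from .claims import AGE_BANDS, ClaimsBundle
from .codes import (
    FRAGILITY_CLASSES,
    HIP_CLASSES,
    PROCEDURE_PRIORITY,
    QUALIFYING_PROCEDURES,
    SURGICAL_PROCEDURES,
)

DEFAULT_INDEX_WINDOW = ("2014-10", "2015-10")

EXCLUSION_REASONS = (
    "age",
    "prior_fracture",
    "insufficient_pre_enrollment",
    "late_surgery",
    "no_qualifying_procedure",
    "outside_window",
)

COHORT_COLUMNS = [
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

_MIN_ADULT = AGE_BANDS.index("60-64")


class ConsistencyError(ValueError):
    """A candidate references a person absent from the individuals table."""


@dataclass
class Candidate:
    person_id: str
    index_month: str
    admission_date: str
    discharge_date: str
    prefecture: int


def find_candidate_events(
    bundle: ClaimsBundle, index_window: tuple[str, str] = DEFAULT_INDEX_WINDOW
) -> list[Candidate]:
    """One candidate per person: the earliest index-window month with a
    non-suspicious fragility hip code co-occurring with an admission."""
    lo, hi = index_window
    if months.month_index(lo) > months.month_index(hi):
        raise ValueError(f"index window end {hi} precedes start {lo}")
    dis = bundle.diseases
    frag = dis[
        (dis["suspicious"] == 0)
        & dis["code_class"].isin(FRAGILITY_CLASSES)
        & (dis["month"] >= lo)
        & (dis["month"] <= hi)
    ][["person_id", "month"]].drop_duplicates()
    if frag.empty:
        return []
    adm = bundle.admissions.copy()
    adm["month"] = adm["admission_date"].str.slice(0, 7)
    merged = frag.merge(adm, on=["person_id", "month"], how="inner")
    if merged.empty:
        return []
    merged = merged.sort_values(
        ["person_id", "month", "admission_date", "discharge_date"], kind="mergesort"
    )
    first = merged.groupby("person_id", as_index=False).first()
    return [
        Candidate(
            person_id=r.person_id,
            index_month=r.month,
            admission_date=r.admission_date,
            discharge_date=r.discharge_date,
            prefecture=int(r.prefecture),
        )
        for r in first.itertuples()
    ]


def classify_site(code_classes: set[str] | list[str]) -> str:
    """Anatomical site with femoral-neck priority over extracapsular."""
    present = set(code_classes) & set(FRAGILITY_CLASSES)
    if not present:
        raise ValueError("classify_site requires at least one fragility hip code")
    return "neck" if "neck_fragility" in present else "extracapsular"


def classify_procedure(procedure_classes: set[str] | list[str]) -> str:
    """Highest-priority qualifying procedure: THR > bipolar > ORIF > conservative."""
    present = set(procedure_classes) & set(QUALIFYING_PROCEDURES)
    if not present:
        raise ValueError("classify_procedure requires at least one qualifying procedure")
    return min(present, key=PROCEDURE_PRIORITY.__getitem__)


def flag_death_within_6m(death_month: str, index_month: str) -> bool:
    """True iff death falls in the index month or the following 5 months."""
    if not death_month:
        return False
    d = months.month_index(death_month) - months.month_index(index_month)
    return 0 <= d <= 5


def apply_eligibility(
    candidates: list[Candidate],
    bundle: ClaimsBundle,
    *,
    max_surgery_day: int = 16,
    min_pre_months: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion/exclusion rules; return (cohort, exclusion log).

    The cohort frame has COHORT_COLUMNS (cci_score left at -1 for the
    comorbidity module to fill); the log has one row per excluded candidate
    with the first failing rule as its reason.
    """
    indiv = bundle.individuals.set_index("person_id")
    dis = bundle.diseases
    hip = dis[(dis["suspicious"] == 0) & dis["code_class"].isin(HIP_CLASSES)]
    hip_by_person = {pid: g for pid, g in hip.groupby("person_id")}
    proc_by_person = {pid: g for pid, g in bundle.procedures.groupby("person_id")}

    kept: list[dict] = []
    excluded: list[dict] = []

    def log(c: Candidate, reason: str, detail: str) -> None:
        excluded.append({"person_id": c.person_id, "reason": reason, "detail": detail})

    for c in candidates:
        if c.person_id not in indiv.index:
            raise ConsistencyError(f"candidate {c.person_id} not in individuals table")
        person = indiv.loc[c.person_id]

        if AGE_BANDS.index(person["age_band"]) < _MIN_ADULT:
            log(c, "age", f"age_band {person['age_band']}")
            continue

        own_hip = hip_by_person.get(c.person_id)
        prior = own_hip[own_hip["month"] < c.index_month] if own_hip is not None else None
        if prior is not None and len(prior):
            log(c, "prior_fracture", f"hip code in {prior['month'].min()}")
            continue

        pre_months = months.month_index(c.index_month) - months.month_index(
            person["enrollment_start_month"]
        )
        if pre_months < min_pre_months:
            log(
                c,
                "insufficient_pre_enrollment",
                f"{pre_months} enrolled months before index",
            )
            continue

        adm_date = months.parse_date(c.admission_date)
        dis_date = (
            months.parse_date(c.discharge_date)
            if c.discharge_date
            else adm_date + dt.timedelta(days=365)
        )
        own_proc = proc_by_person.get(c.person_id)
        linked: pd.DataFrame | None = None
        if own_proc is not None:
            sel = (own_proc["date"] >= adm_date.isoformat()) & (
                own_proc["date"] <= dis_date.isoformat()
            )
            linked = own_proc[sel & own_proc["procedure_class"].isin(QUALIFYING_PROCEDURES)]
        if linked is None or linked.empty:
            log(c, "no_qualifying_procedure", "no qualifying procedure linked to admission")
            continue

        surgical = linked[linked["procedure_class"].isin(SURGICAL_PROCEDURES)]
        if len(surgical):
            first_day = (
                months.parse_date(surgical["date"].min()) - adm_date
            ).days + 1  # admission day = day 1
            if first_day > max_surgery_day:
                log(c, "late_surgery", f"earliest surgery on day {first_day}")
                continue
            procedure = classify_procedure(linked["procedure_class"])
        else:
            procedure = "conservative"

        at_index = dis[
            (dis["person_id"] == c.person_id)
            & (dis["month"] == c.index_month)
            & (dis["suspicious"] == 0)
        ]
        site = classify_site(at_index["code_class"])

        kept.append(
            {
                "person_id": c.person_id,
                "sex": person["sex"],
                "age_band": person["age_band"],
                "prefecture": c.prefecture,
                "index_month": c.index_month,
                "admission_date": c.admission_date,
                "site": site,
                "procedure_class": procedure,
                "died_within_6m": flag_death_within_6m(
                    person["death_month"], c.index_month
                ),
                "cci_score": -1,
            }
        )

    cohort = pd.DataFrame(kept, columns=COHORT_COLUMNS)
    exclusions = pd.DataFrame(excluded, columns=["person_id", "reason", "detail"])
    return cohort, exclusions


def build_cohort(
    bundle: ClaimsBundle,
    index_window: tuple[str, str] = DEFAULT_INDEX_WINDOW,
    *,
    cci_weights: pd.DataFrame | None = None,
    max_surgery_day: int = 16,
    min_pre_months: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidates → eligibility → CCI scores; returns (cohort, exclusions)."""
    from .comorbidity import cci_scores

    candidates = find_candidate_events(bundle, index_window)
    cohort, exclusions = apply_eligibility(
        candidates, bundle, max_surgery_day=max_surgery_day, min_pre_months=min_pre_months
    )
    if len(cohort):
        cohort["cci_score"] = cci_scores(cohort, bundle, weights=cci_weights).to_numpy()
    return cohort, exclusions
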