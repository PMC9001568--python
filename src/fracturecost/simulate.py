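"""Seeded synthetic generator for monthly claims with known ground truth.

The generator emulates the statistical structure the incremental-payment
analysis assumes in a national claims extract: an insured population aged
60+, monthly payment totals per service category, zero-inflated right-
skewed background costs, incident fragility hip-fracture events inside a
13-month index window (new fragility disease codes co-occurring with an
admission and a linked procedure), a large transient inpatient cost surge
with small negative outpatient offsets over the six post-admission months,
deaths within six months (more frequent in men), and the contaminants the
cohort filters must handle: prior hip-fracture codes, short enrollment,
late surgery, fracture codes with no linked procedure, suspicious-flagged
diagnoses, and comorbidity codes.

Every person is generated from pseudo-random streams keyed by
``(seed, stream, person_index)``, so enlarging the population never
reshuffles earlier individuals, and the same config+seed reproduces the
same bundle bit for bit. The config records its implied true six-month
incremental cost (``true_incremental_mean_yen``) for parameter-recovery
tests, and every generated index event carries a ground-truth row with its
by-design eligibility label.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import months
from .claims import AGE_BANDS, ClaimsBundle, normalize_bundle

# pseudo-random stream ids (per table family, per person)
_S_PERSON = 0
_S_COSTS = 1
_S_COMORBID = 2

ADULT_BANDS = AGE_BANDS[1:]  # 60-64 … 95+

# one representative ICD-10-style code per CCI category, used when emitting
# comorbidity disease records
_CCI_REP_CODE = {
    "myocardial_infarction": "I21",
    "congestive_heart_failure": "I50",
    "peripheral_vascular_disease": "I70",
    "cerebrovascular_disease": "I63",
    "dementia": "F03",
    "chronic_pulmonary_disease": "J44",
    "rheumatic_disease": "M05",
    "peptic_ulcer_disease": "K25",
    "mild_liver_disease": "K74",
    "diabetes_without_complication": "E119",
    "diabetes_with_complication": "E112",
    "hemiplegia_paraplegia": "G81",
    "renal_disease": "N18",
    "malignancy": "C61",
    "moderate_severe_liver_disease": "K721",
    "metastatic_solid_tumor": "C78",
    "aids_hiv": "B20",
}

_HIP_CODE = {
    "neck_fragility": "HIPFX-NECK-FRAG-A",
    "extracapsular_fragility": "HIPFX-EXTRACAP-FRAG-A",
    "hip_other": "HIPFX-OPEN-A",
}
_PROC_CODE = {
    "thr": "PROC-THR-A",
    "bipolar": "PROC-BHA-A",
    "orif": "PROC-ORIF-A",
    "conservative": "PROC-CONS-A",
}


class CategoryCost(BaseModel):
    """Zero-inflated gamma model for one category's monthly payment.

    ``mean_yen`` is the unconditional monthly mean; with probability
    ``p_zero`` the month has no claim, otherwise the amount is gamma with
    mean ``mean_yen / (1 - p_zero)`` and shape ``shape``.
    """

    mean_yen: float = Field(ge=0)
    shape: float = Field(default=1.2, gt=0)
    p_zero: float = Field(default=0.0, ge=0, lt=1)


def _default_age_sex_distribution() -> dict[str, dict[str, float]]:
    # rough shape of the Japanese 60+ insured population; normalized on use
    male = [0.090, 0.095, 0.080, 0.060, 0.040, 0.022, 0.008, 0.002]
    female = [0.100, 0.108, 0.095, 0.080, 0.068, 0.050, 0.028, 0.012]
    return {
        band: {"male": m, "female": f}
        for band, m, f in zip(ADULT_BANDS, male, female)
    }


def _default_hazard() -> dict[str, dict[str, float]]:
    # monthly first-fracture hazard by band; steeply age-graded, higher in
    # women; enriched relative to national incidence so that desk-scale
    # samples yield informative cohorts
    base = [0.0008, 0.0012, 0.0020, 0.0035, 0.0060, 0.0090, 0.0130, 0.0160]
    return {
        band: {"male": h, "female": round(1.3 * h, 6)}
        for band, h in zip(ADULT_BANDS, base)
    }


def _default_background_cost() -> dict[str, CategoryCost]:
    return {
        "inpatient": CategoryCost(mean_yen=12_000, shape=1.0, p_zero=0.94),
        "outpatient_facility": CategoryCost(mean_yen=22_000, shape=1.2, p_zero=0.30),
        "outpatient_pharmacy": CategoryCost(mean_yen=11_000, shape=1.2, p_zero=0.45),
        "excluded_other": CategoryCost(mean_yen=2_000, shape=1.0, p_zero=0.80),
    }


def _default_effect() -> dict[str, list[float]]:
    # additive shift of the monthly mean in post months 0..5; the inpatient
    # surge dominates, outpatient use falls while the patient is
    # hospitalized; totals: +2,570,000 − 40,000 − 30,000 = 2,500,000 yen
    return {
        "inpatient": [1_600_000, 600_000, 180_000, 90_000, 60_000, 40_000],
        "outpatient_facility": [-14_000, -10_000, -6_000, -4_000, -3_000, -3_000],
        "outpatient_pharmacy": [-9_000, -6_000, -5_000, -4_000, -3_000, -3_000],
    }


def _default_procedure_mix() -> dict[str, dict[str, float]]:
    return {
        "neck": {"thr": 0.04, "bipolar": 0.59, "orif": 0.34, "conservative": 0.03},
        "extracapsular": {"thr": 0.0, "bipolar": 0.0, "orif": 0.955, "conservative": 0.045},
    }


def _default_cci_prevalence() -> dict[str, float]:
    return {
        "myocardial_infarction": 0.04,
        "congestive_heart_failure": 0.10,
        "peripheral_vascular_disease": 0.05,
        "cerebrovascular_disease": 0.12,
        "dementia": 0.15,
        "chronic_pulmonary_disease": 0.10,
        "rheumatic_disease": 0.04,
        "peptic_ulcer_disease": 0.08,
        "mild_liver_disease": 0.05,
        "diabetes_without_complication": 0.20,
        "diabetes_with_complication": 0.06,
        "hemiplegia_paraplegia": 0.03,
        "renal_disease": 0.08,
        "malignancy": 0.08,
        "moderate_severe_liver_disease": 0.01,
        "metastatic_solid_tumor": 0.01,
        "aids_hiv": 0.001,
    }


class GeneratorConfig(BaseModel):
    """Full parameterization of the synthetic claims population."""

    n_individuals: int = Field(default=5000, ge=0)
    seed: int = 0
    data_window: tuple[str, str] = ("2014-04", "2016-03")
    index_window: tuple[str, str] = ("2014-10", "2015-10")
    age_sex_distribution: dict[str, dict[str, float]] = Field(
        default_factory=_default_age_sex_distribution
    )
    monthly_fracture_hazard: dict[str, dict[str, float]] = Field(
        default_factory=_default_hazard
    )
    prior_fracture_prevalence: float = Field(default=0.03, ge=0, le=1)
    p_insufficient_enrollment: float = Field(default=0.02, ge=0, le=1)
    background_cost: dict[str, CategoryCost] = Field(
        default_factory=_default_background_cost
    )
    background_trend_yen_per_month: float = 0.0
    fracture_cost_effect: dict[str, list[float]] = Field(default_factory=_default_effect)
    effect_shape: float = Field(default=4.0, gt=0)
    p_death_within6: dict[str, float] = Field(
        default_factory=lambda: {"male": 0.115, "female": 0.05}
    )
    p_late_surgery: float = Field(default=0.02, ge=0, le=1)
    p_no_linked_procedure: float = Field(default=0.01, ge=0, le=1)
    site_mix_neck: dict[str, float] = Field(
        default_factory=lambda: {"male": 0.580, "female": 0.561}
    )
    p_second_site_code: float = Field(default=0.08, ge=0, le=1)
    procedure_mix: dict[str, dict[str, float]] = Field(
        default_factory=_default_procedure_mix
    )
    suspicious_flag_rate: float = Field(default=0.05, ge=0, le=1)
    p_suspicious_hip_code: float = Field(default=0.01, ge=0, le=1)
    cci_category_prevalence: dict[str, float] = Field(
        default_factory=_default_cci_prevalence
    )

    @model_validator(mode="after")
    def _validate(self) -> "GeneratorConfig":
        bad: list[str] = []
        if months.month_index(self.data_window[0]) > months.month_index(self.data_window[1]):
            bad.append("data_window")
        iw0, iw1 = (months.month_index(m) for m in self.index_window)
        if iw0 > iw1:
            bad.append("index_window")
        if months.month_index(self.data_window[0]) > iw0 - 6:
            bad.append("index_window: needs 6 pre months inside data_window")
        if months.month_index(self.data_window[1]) < iw1 + 5:
            bad.append("index_window: needs 6 post months inside data_window")
        for band, d in self.age_sex_distribution.items():
            if band not in ADULT_BANDS or any(w < 0 for w in d.values()):
                bad.append(f"age_sex_distribution[{band}]")
        for band, d in self.monthly_fracture_hazard.items():
            if any(not 0 <= h <= 1 for h in d.values()):
                bad.append(f"monthly_fracture_hazard[{band}]")
        for sex, p in self.p_death_within6.items():
            if not 0 <= p <= 1:
                bad.append(f"p_death_within6[{sex}]")
        for sex, p in self.site_mix_neck.items():
            if not 0 <= p <= 1:
                bad.append(f"site_mix_neck[{sex}]")
        for site, mix in self.procedure_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9 or any(p < 0 for p in mix.values()):
                bad.append(f"procedure_mix[{site}]")
        for cat, effects in self.fracture_cost_effect.items():
            if cat not in self.background_cost:
                bad.append(f"fracture_cost_effect[{cat}]: unknown category")
                continue
            if len(effects) != 6:
                bad.append(f"fracture_cost_effect[{cat}]: needs 6 monthly values")
                continue
            mean = self.background_cost[cat].mean_yen
            if any(mean + e < 0 for e in effects):
                bad.append(f"fracture_cost_effect[{cat}]: drives monthly mean below 0")
        for cat, p in self.cci_category_prevalence.items():
            if not 0 <= p <= 1:
                bad.append(f"cci_category_prevalence[{cat}]")
        if bad:
            raise ValueError("invalid generator config: " + "; ".join(bad))
        return self

    @property
    def true_incremental_mean_yen(self) -> float:
        """Implied 6-month total incremental cost among uncensored cases."""
        return float(sum(sum(v) for v in self.fracture_cost_effect.values()))


@dataclass
class GroundTruth:
    """By-design labels for every generated index event."""

    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    true_incremental_mean_yen: float = 0.0

    EVENT_COLUMNS = (
        "person_id",
        "sex",
        "age_band",
        "prefecture",
        "index_month",
        "admission_date",
        "site",
        "procedure_class",
        "exclusion_reason",
        "died_within_6m",
        "death_month",
    )

    def eligible(self) -> pd.DataFrame:
        return self.events[self.events["exclusion_reason"] == ""].reset_index(drop=True)


def _rng(seed: int, stream: int, person: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, person]))


def _draw_amount(rng: np.random.Generator, mean: float, model: CategoryCost) -> int:
    """One monthly amount: zero-inflated gamma with unconditional mean ``mean``."""
    if mean <= 0:
        return 0
    if model.p_zero > 0 and rng.random() < model.p_zero:
        return 0
    cond_mean = mean / (1.0 - model.p_zero)
    return int(round(rng.gamma(model.shape, cond_mean / model.shape)))


def simulate_population(config: GeneratorConfig) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate a claims bundle and its ground truth, deterministically.

    Fracture events draw an admission date uniformly within the index
    month; the linked procedure date is the admission date plus a surgical
    delay concentrated on days 1–3 (a configurable tail lands past day 16);
    post-fracture payment effects shift the monthly cost means for months
    0..5 after the index month; deaths truncate payments after the death
    month; prior-fracture individuals carry a hip code before the index
    window.
    """
    cfg = config
    seed = cfg.seed
    data_lo, data_hi = (months.month_index(m) for m in cfg.data_window)
    iw_lo, iw_hi = (months.month_index(m) for m in cfg.index_window)
    index_months = list(range(iw_lo, iw_hi + 1))

    cells = [
        (band, sex, w)
        for band, d in cfg.age_sex_distribution.items()
        for sex, w in d.items()
        if w > 0
    ]
    weights = np.array([w for _, _, w in cells], dtype=float)
    weights /= weights.sum()

    indiv_rows: list[dict] = []
    pay_rows: list[dict] = []
    dis_rows: list[dict] = []
    proc_rows: list[dict] = []
    adm_rows: list[dict] = []
    gt_rows: list[dict] = []

    categories = list(cfg.background_cost)
    effects = {c: cfg.fracture_cost_effect.get(c, [0.0] * 6) for c in categories}

    for i in range(cfg.n_individuals):
        rng = _rng(seed, _S_PERSON, i)
        pid = f"P{i:06d}"
        band, sex, _ = cells[rng.choice(len(cells), p=weights)]
        prefecture = int(rng.integers(1, 48))

        hazard = cfg.monthly_fracture_hazard.get(band, {}).get(sex, 0.0)
        u = rng.random(len(index_months))
        hit = np.nonzero(u < hazard)[0]
        index_m = index_months[hit[0]] if hit.size else None

        # by-design contaminants, mutually exclusive, priority mirrors the
        # cohort filter order so ground-truth labels match the filter's log
        exclusion = ""
        if rng.random() < cfg.prior_fracture_prevalence:
            exclusion = "prior_fracture"
        elif index_m is not None and rng.random() < cfg.p_insufficient_enrollment:
            exclusion = "insufficient_pre_enrollment"

        enroll_lo = data_lo
        if exclusion == "insufficient_pre_enrollment":
            enroll_lo = index_m - int(rng.integers(0, 6))  # 0..5 pre months
        enroll_hi = data_hi

        # prior hip code strictly before the index window
        if exclusion == "prior_fracture":
            m = int(rng.integers(max(enroll_lo, data_lo), iw_lo))
            cls = ("neck_fragility", "extracapsular_fragility", "hip_other")[
                int(rng.integers(0, 3))
            ]
            dis_rows.append(
                {
                    "person_id": pid,
                    "month": months.month_str(m),
                    "code": _HIP_CODE[cls],
                    "suspicious": 0,
                }
            )

        # occasional suspicious-flagged hip code with no admission: must
        # never create a candidate or break the washout
        if rng.random() < cfg.p_suspicious_hip_code:
            m = int(rng.integers(enroll_lo, enroll_hi + 1))
            dis_rows.append(
                {
                    "person_id": pid,
                    "month": months.month_str(m),
                    "code": _HIP_CODE["neck_fragility"],
                    "suspicious": 1,
                }
            )

        site = procedure = ""
        death_m: int | None = None
        adm_date: dt.date | None = None
        if index_m is not None:
            month_s = months.month_str(index_m)
            day = int(rng.integers(1, months.days_in_month(month_s) + 1))
            adm_date = dt.date(index_m // 12, index_m % 12 + 1, day)

            site = "neck" if rng.random() < cfg.site_mix_neck[sex] else "extracapsular"
            mix = cfg.procedure_mix[site]
            procs, probs = zip(*mix.items())
            procedure = procs[rng.choice(len(procs), p=np.array(probs) / sum(probs))]

            # disease codes at index: the true site's code, plus sometimes a
            # second-site code that the neck-priority rule must resolve
            dis_rows.append(
                {
                    "person_id": pid,
                    "month": month_s,
                    "code": _HIP_CODE[
                        "neck_fragility" if site == "neck" else "extracapsular_fragility"
                    ],
                    "suspicious": 0,
                }
            )
            if site == "neck" and rng.random() < cfg.p_second_site_code:
                dis_rows.append(
                    {
                        "person_id": pid,
                        "month": month_s,
                        "code": _HIP_CODE["extracapsular_fragility"],
                        "suspicious": 0,
                    }
                )

            if exclusion == "" and rng.random() < cfg.p_no_linked_procedure:
                exclusion = "no_qualifying_procedure"
            surgical = procedure in ("thr", "bipolar", "orif")
            late = (
                exclusion == ""
                and surgical
                and rng.random() < cfg.p_late_surgery
            )
            if late:
                exclusion = "late_surgery"

            proc_date: dt.date | None = None
            if exclusion != "no_qualifying_procedure":
                if late:
                    delay = int(rng.integers(16, 26))  # day 17..26
                elif surgical:
                    delay = int(rng.choice([0, 1, 2, 3], p=[0.5, 0.3, 0.15, 0.05]))
                else:
                    delay = int(rng.integers(0, 3))
                proc_date = adm_date + dt.timedelta(days=delay)
                proc_rows.append(
                    {
                        "person_id": pid,
                        "date": proc_date.isoformat(),
                        "code": _PROC_CODE[procedure],
                    }
                )

            los = int(rng.integers(20, 61))
            discharge = adm_date + dt.timedelta(days=los)
            if proc_date is not None and discharge < proc_date:
                discharge = proc_date + dt.timedelta(days=1)
            adm_rows.append(
                {
                    "person_id": pid,
                    "admission_date": adm_date.isoformat(),
                    "discharge_date": discharge.isoformat(),
                    "prefecture": prefecture,
                }
            )

            # deaths only among by-design-eligible cases, never earlier than
            # the month of the linked procedure, so truncation cannot flip a
            # ground-truth eligibility label
            if exclusion == "" and rng.random() < cfg.p_death_within6.get(sex, 0.0):
                floor_m = index_m
                if proc_date is not None:
                    floor_m = max(floor_m, months.month_index(proc_date.isoformat()[:7]))
                death_m = int(rng.integers(floor_m, index_m + 6))
                enroll_hi = death_m

            gt_rows.append(
                {
                    "person_id": pid,
                    "sex": sex,
                    "age_band": band,
                    "prefecture": prefecture,
                    "index_month": month_s,
                    "admission_date": adm_date.isoformat(),
                    "site": site,
                    "procedure_class": procedure,
                    "exclusion_reason": exclusion,
                    "died_within_6m": death_m is not None,
                    "death_month": months.month_str(death_m) if death_m is not None else "",
                }
            )

        indiv_rows.append(
            {
                "person_id": pid,
                "sex": sex,
                "age_band": band,
                "prefecture": prefecture,
                "enrollment_start_month": months.month_str(enroll_lo),
                "enrollment_end_month": months.month_str(enroll_hi),
                "death_month": months.month_str(death_m) if death_m is not None else "",
            }
        )

        # monthly payments over the enrolled span
        crng = _rng(seed, _S_COSTS, i)
        for m in range(enroll_lo, enroll_hi + 1):
            rel = None
            if index_m is not None and 0 <= m - index_m <= 5:
                rel = m - index_m
            for cat in categories:
                model = cfg.background_cost[cat]
                mean = model.mean_yen + cfg.background_trend_yen_per_month * (m - data_lo)
                if rel is not None:
                    eff = effects[cat][rel]
                    if cat == "inpatient" and eff > 0:
                        # skewed per-person surge with exact mean ``eff``
                        pf = crng.gamma(cfg.effect_shape, 1.0 / cfg.effect_shape)
                        amt = _draw_amount(crng, mean, model) + int(round(eff * pf))
                        if amt > 0:
                            pay_rows.append(
                                {
                                    "person_id": pid,
                                    "month": months.month_str(m),
                                    "category": cat,
                                    "amount_yen": amt,
                                }
                            )
                        continue
                    mean = mean + eff
                amt = _draw_amount(crng, mean, model)
                if amt > 0:
                    pay_rows.append(
                        {
                            "person_id": pid,
                            "month": months.month_str(m),
                            "category": cat,
                            "amount_yen": amt,
                        }
                    )

        # comorbidity disease records, any enrolled month
        drng = _rng(seed, _S_COMORBID, i)
        for cat, prev in cfg.cci_category_prevalence.items():
            if drng.random() < prev:
                n_rec = int(drng.integers(1, 4))
                for _ in range(n_rec):
                    m = int(drng.integers(enroll_lo, enroll_hi + 1))
                    dis_rows.append(
                        {
                            "person_id": pid,
                            "month": months.month_str(m),
                            "code": _CCI_REP_CODE[cat],
                            "suspicious": int(drng.random() < cfg.suspicious_flag_rate),
                        }
                    )

    def frame(rows: list[dict], table: str) -> pd.DataFrame:
        from .claims import TABLE_COLUMNS

        if rows:
            return pd.DataFrame(rows)
        return pd.DataFrame({c: [] for c in TABLE_COLUMNS[table]})

    bundle = normalize_bundle(
        individuals=frame(indiv_rows, "individuals"),
        payments=frame(pay_rows, "payments"),
        diseases=frame(dis_rows, "diseases"),
        procedures=frame(proc_rows, "procedures"),
        admissions=frame(adm_rows, "admissions"),
    )
    events = (
        pd.DataFrame(gt_rows, columns=list(GroundTruth.EVENT_COLUMNS))
        .sort_values("person_id", kind="mergesort", ignore_index=True)
    )
    truth = GroundTruth(
        events=events, true_incremental_mean_yen=cfg.true_incremental_mean_yen
    )
    return bundle, truth


def make_filter_fixture() -> tuple[ClaimsBundle, GroundTruth]:
    """Hand-built six-person bundle: one person per eligibility rule.

    F1 fully eligible; F2 under 60; F3 prior hip code (open fracture);
    F4 fewer than 6 pre-index enrolled months; F5 surgery on day 20 of the
    admission; F6 fragility code and admission but no linked qualifying
    procedure. The cohort filter must keep exactly F1.
    """
    indiv = pd.DataFrame(
        [
            ("F1", "female", "80-84", 13, "2014-04", "2016-03", ""),
            ("F2", "male", "<60", 13, "2014-04", "2016-03", ""),
            ("F3", "female", "75-79", 13, "2014-04", "2016-03", ""),
            ("F4", "male", "70-74", 13, "2014-11", "2016-03", ""),
            ("F5", "female", "85-89", 13, "2014-04", "2016-03", ""),
            ("F6", "male", "80-84", 13, "2014-04", "2016-03", ""),
        ],
        columns=[
            "person_id",
            "sex",
            "age_band",
            "prefecture",
            "enrollment_start_month",
            "enrollment_end_month",
            "death_month",
        ],
    )
    dis = []
    adm = []
    proc = []
    pay = []
    for pid in ("F1", "F2", "F3", "F4", "F5", "F6"):
        dis.append((pid, "2015-01", "HIPFX-NECK-FRAG-A", 0))
        adm.append((pid, "2015-01-05", "2015-02-10", 13))
    dis.append(("F3", "2014-06", "HIPFX-OPEN-A", 0))
    proc += [
        ("F1", "2015-01-06", "PROC-BHA-A"),
        ("F2", "2015-01-06", "PROC-BHA-A"),
        ("F3", "2015-01-06", "PROC-ORIF-A"),
        ("F4", "2015-01-06", "PROC-ORIF-A"),
        ("F5", "2015-01-24", "PROC-ORIF-A"),  # day 20 of admission
    ]
    for pid in ("F1", "F2", "F3", "F4", "F5", "F6"):
        for m in ("2014-07", "2014-08", "2014-09", "2014-10", "2014-11", "2014-12"):
            if pid == "F4" and m < "2014-11":
                continue
            pay.append((pid, m, "outpatient_facility", 10_000))
        pay.append((pid, "2015-01", "inpatient", 1_500_000))
        pay.append((pid, "2015-02", "inpatient", 600_000))

    bundle = normalize_bundle(
        individuals=indiv,
        payments=pd.DataFrame(pay, columns=["person_id", "month", "category", "amount_yen"]),
        diseases=pd.DataFrame(dis, columns=["person_id", "month", "code", "suspicious"]),
        procedures=pd.DataFrame(proc, columns=["person_id", "date", "code"]),
        admissions=pd.DataFrame(
            adm, columns=["person_id", "admission_date", "discharge_date", "prefecture"]
        ),
    )
    events = pd.DataFrame(
        [
            ("F1", "female", "80-84", 13, "2015-01", "2015-01-05", "neck", "bipolar", "", False, ""),
            ("F2", "male", "<60", 13, "2015-01", "2015-01-05", "neck", "bipolar", "age", False, ""),
            ("F3", "female", "75-79", 13, "2015-01", "2015-01-05", "neck", "orif", "prior_fracture", False, ""),
            ("F4", "male", "70-74", 13, "2015-01", "2015-01-05", "neck", "orif", "insufficient_pre_enrollment", False, ""),
            ("F5", "female", "85-89", 13, "2015-01", "2015-01-05", "neck", "orif", "late_surgery", False, ""),
            ("F6", "male", "80-84", 13, "2015-01", "2015-01-05", "neck", "", "no_qualifying_procedure", False, ""),
        ],
        columns=list(GroundTruth.EVENT_COLUMNS),
    )
    return bundle, GroundTruth(events=events, true_incremental_mean_yen=0.0)
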