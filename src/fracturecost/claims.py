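"""Typed schemas and round-trip CSV readers/writers for monthly claims tables.

The interchange format is a logical model of a national claims extract:
five UTF-8 comma-delimited tables with header rows —

- ``individuals.csv``: person_id, sex, age_band, prefecture,
  enrollment_start_month, enrollment_end_month, death_month (empty = alive)
- ``payments.csv``: person_id, month, category, amount_yen
- ``diseases.csv``: person_id, month, code, suspicious (0/1)
- ``procedures.csv``: person_id, date, code
- ``admissions.csv``: person_id, admission_date, discharge_date (may be
  empty), prefecture

Months are ISO "YYYY-MM", dates ISO "YYYY-MM-DD", amounts integer yen
(reimbursement plus copayment combined; integers avoid float drift in
sums). Payment categories are normalized to the four-way partition
{inpatient, outpatient_facility, outpatient_pharmacy, excluded_other}:
service tokens the analysis excludes by design (dental, meals, living
costs during hospitalization, home nursing, prosthetic devices, judo
therapist, massage, acupuncture, moxibustion) are routed to
``excluded_other`` on read. Duplicate (person, month, category) payment
rows are summed. Reading a written bundle reproduces it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from . import months
from .codes import classify_disease_codes, classify_procedure_codes

SEXES = ("male", "female")

# "<60" exists so that under-age records can be represented (and excluded);
# the analysis cohort itself starts at 60-64.
AGE_BANDS = (
    "<60",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80-84",
    "85-89",
    "90-94",
    "95+",
)

PAYMENT_CATEGORIES = (
    "inpatient",
    "outpatient_facility",
    "outpatient_pharmacy",
    "excluded_other",
)
CORE_CATEGORIES = PAYMENT_CATEGORIES[:3]

# service tokens excluded from the expenditure definition; all normalize to
# excluded_other and never enter category or total deltas
EXCLUDED_SERVICE_TOKENS = (
    "dental",
    "meal",
    "living_during_hospitalization",
    "home_nursing",
    "prosthetic_device",
    "judo_therapist",
    "massage",
    "acupuncture",
    "moxibustion",
)

TABLE_COLUMNS: dict[str, list[str]] = {
    "individuals": [
        "person_id",
        "sex",
        "age_band",
        "prefecture",
        "enrollment_start_month",
        "enrollment_end_month",
        "death_month",
    ],
    "payments": ["person_id", "month", "category", "amount_yen"],
    "diseases": ["person_id", "month", "code", "suspicious"],
    "procedures": ["person_id", "date", "code"],
    "admissions": ["person_id", "admission_date", "discharge_date", "prefecture"],
}

# columns derived on normalization, never serialized
_DERIVED = {
    "diseases": ["code_class", "cci_category"],
    "procedures": ["procedure_class"],
}


class SchemaError(ValueError):
    """A table is missing a required column."""


class ValidationError(ValueError):
    """A table row violates the schema (bad token, bad month, ...)."""


@dataclass
class ClaimsBundle:
    """The five linked claims tables for a population, normalized."""

    individuals: pd.DataFrame
    payments: pd.DataFrame
    diseases: pd.DataFrame
    procedures: pd.DataFrame
    admissions: pd.DataFrame

    def equals(self, other: "ClaimsBundle") -> bool:
        return all(
            getattr(self, f.name).reset_index(drop=True).equals(
                getattr(other, f.name).reset_index(drop=True)
            )
            for f in fields(self)
        )


def _require_columns(df: pd.DataFrame, table: str) -> None:
    for col in TABLE_COLUMNS[table]:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing required column '{col}'")


def _check_tokens(series: pd.Series, allowed: tuple[str, ...], what: str) -> None:
    bad = ~series.isin(allowed)
    if bad.any():
        i = int(series.index[bad][0])
        raise ValidationError(f"unknown {what} {series[bad].iloc[0]!r} at row {i}")


def _check_months(series: pd.Series, what: str) -> None:
    bad = ~series.map(months.is_month)
    if bad.any():
        i = int(series.index[bad][0])
        raise ValidationError(f"invalid {what} {series[bad].iloc[0]!r} at row {i}")


def _check_dates(series: pd.Series, what: str) -> None:
    bad = ~series.map(months.is_date)
    if bad.any():
        i = int(series.index[bad][0])
        raise ValidationError(f"invalid {what} {series[bad].iloc[0]!r} at row {i}")


def normalize_bundle(
    individuals: pd.DataFrame,
    payments: pd.DataFrame,
    diseases: pd.DataFrame,
    procedures: pd.DataFrame,
    admissions: pd.DataFrame,
) -> ClaimsBundle:
    """Validate raw tables, normalize tokens/dtypes, derive code classes.

    Payment category tokens on the excluded-service list are mapped to
    ``excluded_other``; duplicate (person, month, category) payments are
    summed; tables are sorted into a canonical order so that a written
    bundle is byte-stable.
    """
    individuals = individuals.copy()
    _require_columns(individuals, "individuals")
    individuals["person_id"] = individuals["person_id"].astype(str)
    for _c in ("sex", "age_band", "enrollment_start_month", "enrollment_end_month"):
        individuals[_c] = individuals[_c].astype(str)
    _check_tokens(individuals["sex"], SEXES, "sex")
    _check_tokens(individuals["age_band"], AGE_BANDS, "age_band")
    individuals["prefecture"] = individuals["prefecture"].astype("int64")
    if not individuals["prefecture"].between(1, 47).all():
        raise ValidationError("prefecture outside 1..47 in individuals")
    _check_months(individuals["enrollment_start_month"], "enrollment_start_month")
    _check_months(individuals["enrollment_end_month"], "enrollment_end_month")
    individuals["death_month"] = individuals["death_month"].fillna("").astype(str)
    has_death = individuals["death_month"] != ""
    _check_months(individuals.loc[has_death, "death_month"], "death_month")
    start = individuals["enrollment_start_month"].map(months.month_index)
    end = individuals["enrollment_end_month"].map(months.month_index)
    if (start > end).any():
        raise ValidationError("enrollment_start_month after enrollment_end_month")
    dm = individuals.loc[has_death, "death_month"].map(months.month_index)
    if ((dm < start[has_death]) | (dm > end[has_death])).any():
        raise ValidationError("death_month outside enrollment span")
    if individuals["person_id"].duplicated().any():
        raise ValidationError("duplicate person_id in individuals")
    individuals = individuals[TABLE_COLUMNS["individuals"]].sort_values(
        "person_id", kind="mergesort", ignore_index=True
    )

    payments = payments.copy()
    _require_columns(payments, "payments")
    payments["person_id"] = payments["person_id"].astype(str)
    payments["month"] = payments["month"].astype(str)
    _check_months(payments["month"], "payment month")
    payments["category"] = payments["category"].astype(str).replace(
        {t: "excluded_other" for t in EXCLUDED_SERVICE_TOKENS}
    )
    _check_tokens(payments["category"], PAYMENT_CATEGORIES, "payment category")
    payments["amount_yen"] = payments["amount_yen"].astype("int64")
    if (payments["amount_yen"] < 0).any():
        raise ValidationError("negative amount_yen in payments")
    payments = (
        payments.groupby(["person_id", "month", "category"], as_index=False)["amount_yen"]
        .sum()
        .sort_values(["person_id", "month", "category"], kind="mergesort", ignore_index=True)
    )[TABLE_COLUMNS["payments"]]

    diseases = diseases.copy()
    _require_columns(diseases, "diseases")
    diseases["person_id"] = diseases["person_id"].astype(str)
    diseases["month"] = diseases["month"].astype(str)
    _check_months(diseases["month"], "disease month")
    diseases["code"] = diseases["code"].astype(str)
    diseases["suspicious"] = diseases["suspicious"].astype("int64")
    if not diseases["suspicious"].isin((0, 1)).all():
        raise ValidationError("suspicious flag must be 0 or 1")
    diseases = diseases.drop_duplicates(
        subset=["person_id", "month", "code", "suspicious"]
    ).sort_values(
        ["person_id", "month", "code", "suspicious"], kind="mergesort", ignore_index=True
    )[TABLE_COLUMNS["diseases"]]
    diseases[["code_class", "cci_category"]] = classify_disease_codes(diseases["code"])

    procedures = procedures.copy()
    _require_columns(procedures, "procedures")
    procedures["person_id"] = procedures["person_id"].astype(str)
    procedures["date"] = procedures["date"].astype(str)
    _check_dates(procedures["date"], "procedure date")
    procedures["code"] = procedures["code"].astype(str)
    procedures = procedures.drop_duplicates().sort_values(
        ["person_id", "date", "code"], kind="mergesort", ignore_index=True
    )[TABLE_COLUMNS["procedures"]]
    procedures["procedure_class"] = classify_procedure_codes(procedures["code"])

    admissions = admissions.copy()
    _require_columns(admissions, "admissions")
    admissions["person_id"] = admissions["person_id"].astype(str)
    admissions["admission_date"] = admissions["admission_date"].astype(str)
    _check_dates(admissions["admission_date"], "admission_date")
    admissions["discharge_date"] = admissions["discharge_date"].fillna("").astype(str)
    has_dis = admissions["discharge_date"] != ""
    _check_dates(admissions.loc[has_dis, "discharge_date"], "discharge_date")
    if (
        admissions.loc[has_dis, "discharge_date"] < admissions.loc[has_dis, "admission_date"]
    ).any():
        raise ValidationError("discharge_date before admission_date")
    admissions["prefecture"] = admissions["prefecture"].astype("int64")
    if not admissions["prefecture"].between(1, 47).all():
        raise ValidationError("prefecture outside 1..47 in admissions")
    admissions = admissions.drop_duplicates().sort_values(
        ["person_id", "admission_date"], kind="mergesort", ignore_index=True
    )[TABLE_COLUMNS["admissions"]]

    return ClaimsBundle(individuals, payments, diseases, procedures, admissions)


def empty_bundle() -> ClaimsBundle:
    frames = {
        name: pd.DataFrame({c: pd.Series(dtype=str) for c in cols})
        for name, cols in TABLE_COLUMNS.items()
    }
    frames["individuals"]["prefecture"] = pd.Series(dtype="int64")
    frames["payments"]["amount_yen"] = pd.Series(dtype="int64")
    frames["diseases"]["suspicious"] = pd.Series(dtype="int64")
    frames["admissions"]["prefecture"] = pd.Series(dtype="int64")
    return normalize_bundle(**frames)


def read_claims_bundle(directory: str | Path) -> ClaimsBundle:
    """Read and normalize the five tables from ``directory``."""
    directory = Path(directory)
    raw = {}
    for name in TABLE_COLUMNS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing claims table: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df = df.replace({"": None}) if name in ("individuals", "admissions") else df
        # only optional fields may be empty; restore "" for them explicitly
        if name == "individuals":
            df["death_month"] = df["death_month"].fillna("")
            for c in ("sex", "age_band", "enrollment_start_month", "enrollment_end_month"):
                if df[c].isna().any():
                    raise ValidationError(f"individuals: empty required field '{c}'")
        if name == "admissions":
            df["discharge_date"] = df["discharge_date"].fillna("")
        raw[name] = df
    return normalize_bundle(**raw)


def write_claims_bundle(bundle: ClaimsBundle, directory: str | Path) -> dict[str, Path]:
    """Write the five tables as CSV; read_claims_bundle round-trips exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, cols in TABLE_COLUMNS.items():
        df = getattr(bundle, name)
        path = directory / f"{name}.csv"
        df[cols].to_csv(path, index=False)
        paths[name] = path
    return paths
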