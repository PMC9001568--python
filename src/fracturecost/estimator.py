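"""Within-person pre/post incremental-payment estimation and reporting.

The estimand is the Kilgore-style incremental payment: for each incident
case, the sum of payments over the six months from the admission month
forward minus the sum over the six months before the admission month,
person by person, in integer yen. Only the three core service categories
(inpatient, outpatient facility, outpatient pharmacy) contribute; months
with no claim — including months after death or disenrollment — count as
zero, with no imputation, matching the base-case inclusion of decedents.

The module follows the Model/Results convention: build an
:class:`IncrementalCostModel` from a cohort and a payments table, call
``fit()``, and use the returned :class:`IncrementalCostResults` for
stratified summaries, the death-exclusion sensitivity analysis, and
annualized population totals (13-month case window scaled by 12/13, exact
rational arithmetic before any rounding; yen→USD at a configurable rate
with half-away-from-zero rounding to a configurable unit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .claims import ClaimsBundle, CORE_CATEGORIES

DELTA_COLUMNS = {
    "inpatient": "delta_inpatient_yen",
    "outpatient_facility": "delta_outpatient_facility_yen",
    "outpatient_pharmacy": "delta_outpatient_pharmacy_yen",
}

STRATIFIERS = ("sex", "age_band", "site", "procedure_class", "prefecture")


def _month_index_vec(m: pd.Series) -> pd.Series:
    return m.str.slice(0, 4).astype(int) * 12 + m.str.slice(5, 7).astype(int) - 1


def round_half_away(amount, unit: int = 1) -> int:
    """Round to the nearest multiple of ``unit``, ties away from zero."""
    if unit <= 0:
        raise ValueError("rounding unit must be positive")
    q = Fraction(amount) / unit
    sign = 1 if q >= 0 else -1
    return int(sign * math.floor(abs(q) + Fraction(1, 2))) * unit


def yen_to_usd(amount_yen, rate: int = 110, rounding_unit: int = 10) -> int:
    """Convert yen to dollars at ``rate`` yen per dollar, rounded to the
    nearest ``rounding_unit`` dollars (10 for per-patient figures, ten
    million for national totals)."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return round_half_away(Fraction(amount_yen) / rate, rounding_unit)


def annualize(mean_yen, n: int, window_months: int = 13) -> Fraction:
    """Annual population total: mean × n × 12 / window, exact."""
    if window_months <= 0:
        raise ValueError("window_months must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")
    return Fraction(mean_yen) * n * 12 / window_months


@dataclass
class AnnualizedTotal:
    stratum: str
    total_yen: int
    total_usd: int
    window_months: int
    annualization_factor: Fraction
    exchange_rate: int


def incremental_payments(cohort: pd.DataFrame, payments: pd.DataFrame) -> pd.DataFrame:
    """Per-person category deltas and total for every cohort member.

    Returns one row per cohort person: person_id, the three category
    deltas, and delta_total_yen = their sum (excluded_other never
    contributes). Persons with no payment rows in either window get zeros.
    """
    base = cohort[["person_id", "index_month"]].copy()
    out = base.copy()
    for col in DELTA_COLUMNS.values():
        out[col] = 0
    if len(cohort) and len(payments):
        pay = payments[payments["category"].isin(CORE_CATEGORIES)].merge(
            base, on="person_id", how="inner"
        )
        if len(pay):
            rel = _month_index_vec(pay["month"]) - _month_index_vec(pay["index_month"])
            sign = np.where(
                (rel >= 0) & (rel <= 5), 1, np.where((rel >= -6) & (rel <= -1), -1, 0)
            )
            pay = pay.assign(signed=sign * pay["amount_yen"].to_numpy())
            sums = (
                pay.groupby(["person_id", "category"], observed=True)["signed"]
                .sum()
                .unstack(fill_value=0)
            )
            for cat, col in DELTA_COLUMNS.items():
                if cat in sums:
                    aligned = (
                        out["person_id"].map(sums[cat]).fillna(0).astype("int64")
                    )
                    out[col] = aligned
    out["delta_total_yen"] = sum(out[c] for c in DELTA_COLUMNS.values())
    return out.drop(columns=["index_month"])


def _summary_rows(df: pd.DataFrame) -> dict:
    row = {"n": int(len(df))}
    for label, col in [("total", "delta_total_yen")] + [
        (cat, col) for cat, col in DELTA_COLUMNS.items()
    ]:
        if len(df):
            row[f"mean_{label}_yen"] = float(df[col].mean())
            row[f"median_{label}_yen"] = float(df[col].median())
        else:
            row[f"mean_{label}_yen"] = float("nan")
            row[f"median_{label}_yen"] = float("nan")
    row["sum_total_yen"] = int(df["delta_total_yen"].sum()) if len(df) else 0
    return row


def summarize(
    increments: pd.DataFrame,
    cohort: pd.DataFrame,
    by: str | list[str] | None = None,
) -> pd.DataFrame:
    """Stratified n / mean / median (overall row always included).

    ``by`` is a cohort column (or list of columns) from
    sex | age_band | site | procedure_class | prefecture; None gives the
    overall row only. Medians with even n are the mean of the two central
    values. An exact integer ``sum_total_yen`` column supports loss-free
    recomposition and annualization.
    """
    unmatched = set(increments["person_id"]) - set(cohort["person_id"])
    if unmatched:
        raise ValueError(f"increments without cohort records: {sorted(unmatched)[:5]}")
    merged = increments.merge(
        cohort.drop(columns=[c for c in cohort.columns if c in increments.columns and c != "person_id"]),
        on="person_id",
        how="inner",
    )
    keys = [by] if isinstance(by, str) else list(by or [])
    rows = []
    if keys:
        for vals, g in merged.groupby(keys, observed=True, sort=True):
            vals = vals if isinstance(vals, tuple) else (vals,)
            rows.append({k: v for k, v in zip(keys, vals)} | _summary_rows(g))
    rows.append({k: "overall" for k in keys} | _summary_rows(merged))
    if not keys:
        rows[-1] = {"stratum": "overall"} | _summary_rows(merged)
    return pd.DataFrame(rows)


def sensitivity_exclude_deaths(
    increments: pd.DataFrame,
    cohort: pd.DataFrame,
    by: str | list[str] | None = None,
) -> pd.DataFrame:
    """The base-case summary restricted to those alive 6 months post-index."""
    alive = cohort[~cohort["died_within_6m"].astype(bool)]
    kept = increments[increments["person_id"].isin(alive["person_id"])]
    return summarize(kept, alive, by=by)


class IncrementalCostModel:
    """Pre/post incremental-payment model for an incident-fracture cohort.

    Parameters
    ----------
    cohort : DataFrame with cohort_builder's COHORT_COLUMNS.
    payments : normalized monthly payments table.
    window_months : length in months of the case-accrual window (13 for an
        October–October index window); annual totals scale by 12/window.
    exchange_rate : yen per US dollar for report conversions.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        payments: pd.DataFrame,
        *,
        window_months: int = 13,
        exchange_rate: int = 110,
    ) -> None:
        if window_months <= 0:
            raise ValueError("window_months must be positive")
        self.cohort = cohort.reset_index(drop=True)
        self.payments = payments
        self.window_months = window_months
        self.exchange_rate = exchange_rate

    @classmethod
    def from_bundle(cls, cohort: pd.DataFrame, bundle: ClaimsBundle, **kwargs):
        return cls(cohort, bundle.payments, **kwargs)

    def fit(self) -> "IncrementalCostResults":
        increments = incremental_payments(self.cohort, self.payments)
        return IncrementalCostResults(self, increments)


class IncrementalCostResults:
    """Fitted per-person increments plus summary/annualization methods."""

    def __init__(self, model: IncrementalCostModel, increments: pd.DataFrame) -> None:
        self.model = model
        self.increments = increments
        self.cohort = model.cohort

    @property
    def n(self) -> int:
        return len(self.cohort)

    def summarize(self, by: str | list[str] | None = None) -> pd.DataFrame:
        return summarize(self.increments, self.cohort, by=by)

    def sensitivity_exclude_deaths(self, by: str | list[str] | None = None) -> pd.DataFrame:
        return sensitivity_exclude_deaths(self.increments, self.cohort, by=by)

    def annualize(
        self,
        by: str | None = "sex",
        *,
        usd_rounding: int = 10_000_000,
    ) -> pd.DataFrame:
        """Annual population totals per stratum, in yen and USD.

        Totals use the exact integer sum of per-person deltas scaled by
        12/window (rational arithmetic); rounding happens only on the
        reported yen (nearest yen) and USD (nearest ``usd_rounding``).
        """
        summ = self.summarize(by=by)
        key = by if by is not None else "stratum"
        rows = []
        for r in summ.itertuples():
            exact = Fraction(int(r.sum_total_yen) * 12, self.model.window_months)
            total_yen = round_half_away(exact)
            rows.append(
                AnnualizedTotal(
                    stratum=str(getattr(r, key)),
                    total_yen=total_yen,
                    total_usd=yen_to_usd(
                        total_yen, self.model.exchange_rate, usd_rounding
                    ),
                    window_months=self.model.window_months,
                    annualization_factor=Fraction(12, self.model.window_months),
                    exchange_rate=self.model.exchange_rate,
                ).__dict__
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary table (overall and by sex, plus annual totals)."""
        lines = ["Incremental medical payments, 6 months post minus 6 months pre"]
        lines.append(f"cases: {self.n}   window: {self.model.window_months} months")
        overall = self.summarize()
        by_sex = self.summarize(by="sex")
        lines.append(f"{'stratum':<12}{'n':>8}{'mean yen':>14}{'median yen':>14}{'mean USD':>10}")
        for frame, key in ((by_sex, "sex"), (overall, "stratum")):
            for r in frame.itertuples():
                name = getattr(r, key)
                if key == "sex" and name == "overall":
                    continue
                mean = r.mean_total_yen
                usd = yen_to_usd(round(mean), self.model.exchange_rate) if r.n else 0
                lines.append(
                    f"{name:<12}{r.n:>8}{round_half_away(mean, 1000) if r.n else 0:>14}"
                    f"{round_half_away(r.median_total_yen, 1000) if r.n else 0:>14}{usd:>10}"
                )
        ann = self.annualize(by=None)
        total = int(ann["total_yen"].iloc[0])
        usd = int(ann["total_usd"].iloc[0])
        lines.append(
            f"annualized population total: {total / 1e9:.2f} billion yen "
            f"({usd / 1e9:.2f} billion USD at {self.model.exchange_rate} yen/USD)"
        )
        return "\n".join(lines)
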