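"""Charlson Comorbidity Index (2011 updated weights) from disease records.

The score for a cohort member sums the 2011-update weights over the
distinct comorbidity categories found in that person's non-suspicious
disease records during the six months up to and including the admission
month (the baseline window of the pre/post design). Severity hierarchies
are applied: within each hierarchy group (liver disease, diabetes,
malignancy) only the most severe category present is scored, so e.g.
metastatic solid tumor (weight 6) suppresses any-malignancy (weight 2).
Duplicate codes and record order never change the score.
"""

from __future__ import annotations

import pandas as pd

from . import months
from .claims import ClaimsBundle
from .codes import cci_weight_table


def _score_categories(categories: set[str], weights: pd.DataFrame) -> int:
    present = weights[weights["category"].isin(categories)]
    score = 0
    for group, g in present.groupby("hierarchy_group"):
        if group == "":
            score += int(g["weight"].sum())
        else:
            score += int(g["weight"].max())  # only the most severe of the pair
    return score


def cci_score(
    person_id: str,
    index_month: str,
    bundle: ClaimsBundle,
    weights: pd.DataFrame | None = None,
) -> int:
    """CCI for one person over months index_month-5 … index_month."""
    if weights is None:
        weights = cci_weight_table()
    lo = months.add_months(index_month, -5)
    dis = bundle.diseases
    rows = dis[
        (dis["person_id"] == person_id)
        & (dis["suspicious"] == 0)
        & (dis["cci_category"] != "")
        & (dis["month"] >= lo)
        & (dis["month"] <= index_month)
    ]
    return _score_categories(set(rows["cci_category"]), weights)


def cci_scores(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    weights: pd.DataFrame | None = None,
) -> pd.Series:
    """Vectorized CCI per cohort row, aligned with the cohort index."""
    if weights is None:
        weights = cci_weight_table()
    dis = bundle.diseases
    cci = dis[(dis["suspicious"] == 0) & (dis["cci_category"] != "")]
    by_person = {pid: g for pid, g in cci.groupby("person_id")}
    out = []
    for r in cohort.itertuples():
        g = by_person.get(r.person_id)
        if g is None:
            out.append(0)
            continue
        lo = months.add_months(r.index_month, -5)
        window = g[(g["month"] >= lo) & (g["month"] <= r.index_month)]
        out.append(_score_categories(set(window["cci_category"]), weights))
    return pd.Series(out, index=cohort.index, name="cci_score")
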