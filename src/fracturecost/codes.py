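"""Bundled code-set tables and code→class lookups.

Hip-fracture disease codes and hip-surgery procedure codes are *synthetic
stand-ins* (files ``synthetic_hip_disease_codes.csv`` and
``synthetic_procedure_codes.csv``): the operational code lists used with
real Japanese claims are restricted, so the bundled sets define the same
class structure (fragility femoral-neck, fragility extracapsular,
open/stress "other hip"; THR / bipolar hip arthroplasty / ORIF /
conservative management) over invented code strings. Both tables are plain
CSV and can be swapped for operational lists without code changes.

Charlson comorbidity scoring uses the 2011 updated weight set over the 17
classical categories with severity hierarchies (liver disease, diabetes,
malignancy), and an ICD-10 prefix mapping in the style of the standard
claims coding algorithms (trimmed to headline prefixes; editable CSV).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

DISEASE_CLASSES = (
    "neck_fragility",
    "extracapsular_fragility",
    "hip_other",
    "cci",
    "other",
)
FRAGILITY_CLASSES = ("neck_fragility", "extracapsular_fragility")
HIP_CLASSES = ("neck_fragility", "extracapsular_fragility", "hip_other")

PROCEDURE_CLASSES = ("thr", "bipolar", "orif", "conservative", "other")
QUALIFYING_PROCEDURES = ("thr", "bipolar", "orif", "conservative")
SURGICAL_PROCEDURES = ("thr", "bipolar", "orif")
# classification priority when several procedures are linked to one admission
PROCEDURE_PRIORITY = {"thr": 0, "bipolar": 1, "orif": 2, "conservative": 3}

CCI_CATEGORIES = (
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "dementia",
    "chronic_pulmonary_disease",
    "rheumatic_disease",
    "peptic_ulcer_disease",
    "mild_liver_disease",
    "diabetes_without_complication",
    "diabetes_with_complication",
    "hemiplegia_paraplegia",
    "renal_disease",
    "malignancy",
    "moderate_severe_liver_disease",
    "metastatic_solid_tumor",
    "aids_hiv",
)


def _data_path(name: str) -> Path:
    return Path(resources.files("fracturecost.data") / name)


@lru_cache(maxsize=None)
def hip_code_table() -> pd.DataFrame:
    return pd.read_csv(_data_path("synthetic_hip_disease_codes.csv"), dtype=str)


@lru_cache(maxsize=None)
def procedure_code_table() -> pd.DataFrame:
    return pd.read_csv(_data_path("synthetic_procedure_codes.csv"), dtype=str)


class CciConfigError(ValueError):
    """Raised when a CCI weight table does not cover the 17 categories."""


def cci_weight_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a CCI weight table (category, weight, hierarchy_group).

    Within a hierarchy_group only the most severe (highest-weight) category
    present for a person is scored.
    """
    df = pd.read_csv(path if path is not None else _data_path("cci_weights.csv"))
    df["hierarchy_group"] = df["hierarchy_group"].fillna("")
    unknown = set(df["category"]) - set(CCI_CATEGORIES)
    missing = set(CCI_CATEGORIES) - set(df["category"])
    if unknown or missing:
        raise CciConfigError(
            f"CCI weight table mismatch: unknown={sorted(unknown)} missing={sorted(missing)}"
        )
    if (df["weight"] < 0).any():
        raise CciConfigError("CCI weights must be non-negative")
    return df


@lru_cache(maxsize=None)
def _cci_prefix_map() -> tuple[dict[str, str], int]:
    df = pd.read_csv(_data_path("cci_icd10_prefixes.csv"), dtype=str)
    mapping = dict(zip(df["prefix"], df["category"]))
    return mapping, max(len(p) for p in mapping)


def cci_category_of(code: str) -> str | None:
    """Longest-prefix ICD-10 lookup; None if the code maps to no category."""
    mapping, maxlen = _cci_prefix_map()
    for cut in range(min(len(code), maxlen), 0, -1):
        cat = mapping.get(code[:cut])
        if cat is not None:
            return cat
    return None


def classify_disease_codes(codes: pd.Series) -> pd.DataFrame:
    """Derive (code_class, cci_category) for each disease-code string.

    Hip codes match exactly against the bundled hip table; anything else is
    tried as an ICD-10-style prefix for a CCI category; the remainder is
    ``other``.
    """
    hip = dict(zip(hip_code_table()["code"], hip_code_table()["code_class"]))

    def one(code: str) -> tuple[str, str]:
        cls = hip.get(code)
        if cls is not None:
            return cls, ""
        cat = cci_category_of(code)
        if cat is not None:
            return "cci", cat
        return "other", ""

    uniq = {c: one(c) for c in codes.unique()}
    out = pd.DataFrame(
        [uniq[c] for c in codes], columns=["code_class", "cci_category"], index=codes.index
    )
    return out


def classify_procedure_codes(codes: pd.Series) -> pd.Series:
    table = dict(zip(procedure_code_table()["code"], procedure_code_table()["procedure_class"]))
    return codes.map(lambda c: table.get(c, "other"))
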