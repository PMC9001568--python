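"""Printed headline estimates from the national claims analysis of
fragility hip fracture in Japan (fiscal 2014–2015) that this pipeline
reimplements.

These constants are *inputs* to the worked-example consistency report:
the underlying person-level claims are restricted, so the arithmetic
identities among the printed numbers (pooled means, annualized totals,
currency conversions) are what can be recomputed at desk scale.
"""

from __future__ import annotations

N_CASES = {"male": 28_868, "female": 113_493}
N_TOTAL = 142_361

MEAN_YEN = {"male": 2_550_000, "female": 2_494_000, "overall": 2_505_000}
MEDIAN_YEN = {"male": 2_369_000, "female": 2_310_000, "overall": 2_321_000}

# annual population totals (13-month accrual scaled by 12/13)
ANNUAL_TOTAL_YEN = {"male": 67.96e9, "female": 261.24e9, "overall": 329.2e9}
ANNUAL_TOTAL_USD = {"male": 620e6, "female": 2.37e9, "overall": 2.99e9}

EXCHANGE_RATE = 110  # yen per US dollar
WINDOW_MONTHS = 13

# procedure payments (reimbursement + copayment), fiscal 2014-2015 schedule
PROCEDURE_FEE_YEN = {"bipolar": 195_000, "orif": 188_000}

DEATH_WITHIN_6M_PCT = {"male": 11.5, "female": 5.0}
SITE_NECK_PCT = {"male": 58.0, "female": 56.1}

# every printed yen / USD pair (label, yen, printed USD)
PRINTED_CONVERSIONS = [
    ("male mean", 2_550_000, 23_180),
    ("male median", 2_369_000, 21_540),
    ("female mean", 2_494_000, 22_670),
    ("female median", 2_310_000, 21_000),
    ("pooled mean", 2_505_000, 22_700),
    ("pooled median", 2_321_000, 21_100),
    ("male inpatient mean", 2_668_000, 24_260),
    ("male inpatient median", 2_464_000, 22_400),
    ("female inpatient mean", 2_568_000, 23_340),
    ("female inpatient median", 2_367_000, 21_520),
    ("neck bipolar male mean", 2_885_000, 26_230),
    ("neck ORIF male mean", 2_227_000, 20_240),
    ("neck bipolar female mean", 2_804_000, 25_490),
    ("neck ORIF female mean", 2_187_000, 19_880),
    ("extracapsular ORIF male mean", 2_444_000, 22_220),
    ("extracapsular ORIF female mean", 2_399_000, 21_810),
    ("prefecture max male mean", 2_991_000, 27_190),
    ("prefecture min male mean", 2_088_000, 18_990),
    ("prefecture max female mean", 3_023_000, 27_490),
    ("prefecture min female mean", 2_087_000, 18_980),
    ("male outpatient facility mean", -76_000, -690),
    ("male outpatient facility median", -21_000, -190),
    ("male pharmacy mean", -42_000, -380),
    ("male pharmacy median", -16_000, -140),
    ("female outpatient facility mean", -41_000, -380),
    ("female outpatient facility median", -15_000, -130),
    ("female pharmacy mean", -32_000, -290),
    ("female pharmacy median", -13_000, -120),
    ("bipolar procedure fee", 195_000, 1_770),
    ("ORIF procedure fee", 188_000, 1_710),
    ("procedure fee difference", 7_000, 70),
]
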