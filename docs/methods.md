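# Methods

## Estimand and identification

The quantity estimated is the six-month incremental medical payment per
incident fragility hip fracture: the difference, within person, between
total payments in the six months from the admission month forward and
the six months before the admission month. Payments are monthly totals
combining insurer reimbursement and patient copayment for three core
service categories — inpatient, outpatient (medical facility), and
outpatient (pharmacy). Dental, meals, living costs during
hospitalization, home nursing, prosthetic devices, judo therapy,
massage, acupuncture and moxibustion are carried in the data model as an
`excluded_other` category that never enters any delta; long-term-care
insurance payments are outside the data model entirely.

Working at month granularity means the admission month is counted as
"post" whether the admission fell on its 1st or its 31st; the pre-window
therefore slightly overstates and the post-window slightly understates
the true post-fracture cost on average. Six-month windows make this a
small fraction of the total. The pre/post difference also absorbs any
background time trend in costs: with a linear monthly trend of slope
*b*, the estimator's bias is exactly 36·*b* (the difference of the two
window sums of an arithmetic progression), a closed form the test suite
verifies. The method assumes stationary background costs; it does not
adjust for regression to the mean or secular trends.

## Case identification and eligibility

A candidate index event is the earliest month inside the index window
(default October 2014 – October 2015, 13 months) with a non-suspicious
fragility hip-fracture disease code (femoral neck or extracapsular)
co-occurring with an admission in that month. One index event per
person; later fractures are never re-counted. Eligibility then requires,
in this order (the first failing rule is logged, one reason per
excluded candidate):

1. **age** — age band 60-64 or older at baseline;
2. **prior_fracture** — washout: no non-suspicious hip-fracture code of
   any class (fragility, open, or stress) in any observed month before
   the index month. The washout is relative to each person's index
   month rather than a fixed calendar interval, which generalizes the
   fixed pre-window special case to arbitrary index months;
3. **insufficient_pre_enrollment** — at least 6 enrolled months strictly
   before the index month;
4. **no_qualifying_procedure / late_surgery** — a qualifying procedure
   (THR, bipolar hemiarthroplasty, ORIF, or conservative management)
   dated within [admission, discharge] of the index admission. If any
   surgery is linked, the earliest must fall on day ≤ 16 of the
   admission, counting the admission day as day 1; day ≥ 17 is excluded
   as a likely in-hospital fracture (the boundary day was ambiguous in
   prose and is resolved here as excluded). Conservative management
   requires an explicit conservative code and no linked surgery; a
   fracture code with no qualifying procedure at all is excluded.

Decedents within the admission month + 5 are retained and flagged
(base case); the sensitivity analysis re-summarizes the survivors only.
Site classification uses femoral-neck priority when codes for both
sites appear; procedure classification uses THR > bipolar > ORIF >
conservative. Prefecture is taken from the index admission (location of
care, not residence). Suspicious-flagged diagnosis records — tentative
codes entered to justify tests — are ignored uniformly: they can
neither create a candidate, break the washout, nor contribute to
comorbidity scoring.

## Comorbidity

The Charlson Comorbidity Index uses the 2011 updated weights over the
17 classical categories (CHF 2, dementia 2, metastatic solid tumor 6,
AIDS/HIV 4; MI, peripheral vascular, cerebrovascular, peptic ulcer and
uncomplicated diabetes 0, etc.), with severity hierarchies: within
liver disease, diabetes, and malignancy groups only the most severe
category present is scored. Categories are detected from
non-suspicious disease records in the six months up to and including
the admission month — CCI is a baseline construct, so the pre-index
reading of "within 6 months of admission including the admission
month" is used. Code→category detection is by longest-prefix ICD-10
match against a bundled, editable CSV in the style of the standard
claims coding algorithms, trimmed to headline prefixes. The hip and
procedure code sets bundled with the package are synthetic stand-ins
(`synthetic_*.csv`): operational code lists for real claims are
restricted, and both tables are designed to be swapped out without code
changes.

## Reporting conventions

All payment arithmetic is integer yen; stratum summaries carry an exact
integer `sum_total_yen` so stratified means recompose the overall mean
with zero rounding loss. Annualization scales the exact sum by 12/13
(13-month accrual window → annual) in rational arithmetic, rounding
only the final figure. Yen means are reported to the nearest 1,000 yen;
USD conversions use ¥110 = $1 with half-away-from-zero rounding to the
nearest $10 per patient and the nearest $10 million for national
totals. The published national estimates are internally inconsistent in
several printed yen/USD pairs (consistent with USD computed from
unrounded means before the yen figures were rounded for print); the
`worked-examples` report recomputes every printed pair and labels those
rows `flagged` instead of silently matching them.

## Synthetic claims generator

The generator emulates what the analysis needs from a national claims
extract, with a recorded ground truth:

- **Population**: individuals aged 60+, age-sex weights shaped like the
  Japanese older population (≈55% female), prefecture uniform 1–47,
  enrollment spanning April 2014 – March 2016.
- **Background costs**: independent zero-inflated gamma monthly amounts
  per category (defaults: outpatient facility mean ¥22,000/month with
  30% zero months; pharmacy ¥11,000 with 45% zeros; inpatient mean
  ¥12,000 arising as rare large stays, 94% zeros) — zero-inflated and
  right-skewed as claims costs are, so medians sit below means. An
  optional linear trend exercises the estimator's documented bias.
- **Fracture events**: monthly hazards steeply age-graded and ~1.3×
  higher in women. Default hazards are enriched relative to national
  incidence so that a few thousand simulated individuals yield an
  informative cohort (≈4–5% fracture over the 13-month window); the
  generator makes no attempt to reproduce national case counts or the
  published national means, which derive from restricted person-level
  data.
- **Post-fracture effect**: additive shifts of the monthly cost means
  for the six post months, inpatient +¥2.57M front-loaded over months
  0–5 with a per-person gamma factor (mean 1, shape 4) for realistic
  skew, outpatient facility −¥40k and pharmacy −¥30k in total —
  matching the sign pattern of observed incremental payments (inpatient
  surge, outpatient suppression during hospitalization). The implied
  true six-month incremental cost, ¥2,500,000 by default, is recorded
  as `true_incremental_mean_yen` and is exact because effects shift
  distribution means.
- **Design contaminants**, each drawn per person and labelled in the
  ground truth: prior hip-fracture codes before the index window (3%),
  short pre-index enrollment (2% of events), late surgery past day 16
  (2% of surgical events, emulating the ~98% within-16-days pattern),
  fracture codes with no linked procedure (1%), suspicious-only hip
  codes (1%), suspicious flags on 5% of comorbidity records; site mix
  neck/extracapsular 58.0/42.0 (men) and 56.1/43.9 (women); procedure
  mixes concentrated on bipolar + ORIF for neck and ORIF for
  extracapsular fractures; six-month death probability 11.5% (men) and
  5.0% (women), truncating all subsequent records.
- **Determinism**: every draw comes from a stream keyed by
  (seed, table-family, person index), so runs are bit-reproducible and
  enlarging the population never reshuffles earlier individuals.

Deaths are drawn only for by-design-eligible cases and never before the
month of the linked procedure; this keeps ground-truth eligibility
labels exactly recoverable by the cohort builder (the oracle-equivalence
tests require zero discrepancies), at the cost of not modelling deaths
among excluded candidates — irrelevant to any estimate the pipeline
reports. What the generator does **not** emulate: per-diem vs
fee-for-service payment mechanics, within-month admission-date effects
on billing, hospital transfers, regional cost variation, age- or
comorbidity-dependent treatment effects, and correlation between
background cost level and fracture risk. Passing tests therefore show
that the pipeline's logic and arithmetic are correct under the stated
generative assumptions, not that real-world confounding is absent.

## Problem sizes and tolerances

The test suite and acceptance script run the generator at 1,200–5,000
individuals (hundreds of cohort cases), sizes chosen so stochastic
checks are statistically meaningful: binomial convergence and
parameter-recovery tests use 3-standard-error bands, the recomposition
and oracle-equivalence checks are exact, and the worked-example
identities are exact integer/rational arithmetic. Degenerate inputs are
defined, not errors: an empty population yields an empty bundle, zero
hazard yields an empty cohort and empty (but well-formed) report
tables, an all-decedent sensitivity stratum reports n = 0 with absent
summaries.

## Known limitations

- Incremental differencing attributes to the fracture any cost change
  coinciding with the post window; the 36·b trend bias is documented
  and tested but not corrected.
- The bundled hip/procedure code tables are synthetic; applying the
  pipeline to real claims requires substituting operational code lists.
- No uncertainty is attached to the cost summaries (means/medians are
  reported without confidence intervals, matching the descriptive
  design), and no regression adjustment is offered.
- The CCI window interpretation (pre-index) is a documented choice; a
  post-admission reading of the same prose would shift scores for
  conditions first coded after admission.
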