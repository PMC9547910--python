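# Methods

## Scope and model

`ccval` implements a criterion-validity analysis for a rule-based
administrative classifier of back-pain chronicity. Two instruments are
compared person by person:

* the **chronicity class** (CC 1/2/3), computed from claims in a closed
  365-day lookback window ending at the invitation date;
* the **GCPS grade** (I–IV), scored from a seven-item self-report at
  enrolment.

For comparison the four grades are collapsed to three (I+II → 1, III → 2,
IV → 3) and, for the dichotomous analysis, to severe (III–IV vs CC 3) and
non-severe. The package treats the classifier as the *prediction* and the
GCPS as the *reference*; it does not re-derive or re-fit the classifier's
rules.

## GCPS scoring

Pain-intensity and disability scores are item means × 10, kept unrounded
(exact thirds). Disability days bin at 7/15/31 days and the disability
score at 30/50/70 points, each contributing 0–3 points; their sum (0–6)
and the intensity score give the grade: ≤ 2 points → I below intensity
50, II at 50 and above; 3–4 points → III; 5–6 points → IV. The
disability-score cutpoints and the intensity threshold follow the
original instrument, since they are the scoring authority the analysed
rule set refers to. Every threshold is inclusive at the upper category, a
single consistent half-open binning. A pain-free grade 0 is deliberately
not modelled — the instrument is applied to a population that enrolled
for back-pain care — so an all-zero response grades I with a warning.
Missing items are hard validation errors: the assessment that the data
model mirrors was mandatory and complete by design.

## Chronicity classification

Window arithmetic is closed on both ends in whole days; a record dated on
either boundary counts. Diagnosis *records* are counted, not distinct
codes or dates, because claims extracts legitimately repeat codes;
deduplication by (code, date) is available but off by default. Decisions
taken where the rule text is ambiguous:

* "two opioid prescriptions within six months" is read as *some pair* of
  N02A prescriptions ≤ 183 days apart inside the lookback year (a sliding
  pair window, not a calendar anchor); with sorted dates, checking
  consecutive gaps is equivalent to checking all pairs;
* the risk-class sick-leave condition ("less than six weeks") requires at
  least one attributed day (1–41); a literal zero-day reading would make
  the risk class absorb every non-chronic case;
* attributed sick-leave days are summed cumulatively across episodes,
  clipped to their overlap with the window;
* "M40–M54" matches any code whose three-character root falls lexically
  in that interval; starred F-codes match by prefix, un-starred
  four/five-digit codes exactly.

Class precedence is 3 → 2 → 1, which makes the three conditions mutually
exclusive; fewer than two back-pain diagnoses is *not classifiable* and
must be filtered before dichotomisation. A vectorised table route
(`classify_table`) mirrors the per-person reference route exactly and is
what the pipeline uses.

## Cohorts

Three nested populations: everyone with ≥ 1 invoice in the 365 days up to
and including enrolment (cost cohort); the invited subset enrolling
within ≤ 90 days of invitation (validation cohort); and the further
subset with daily-sickness-benefit insurance (sensitivity subgroup). The
invoice window anchors at enrolment while the classifier anchors at
invitation — two deliberately different anchors. "Within 90 days" is
inclusive because the excluded group is those who took *more than* 90
days.

## Agreement metrics

Sensitivity, specificity, proportion correct and MCC are computed
directly from the table; MCC returns 0 with a warning on a degenerate
margin so simulations never crash. Cohen's kappa (linear weights by
default on the 3 × 3 comparison; for 2 × 2 tables all weightings coincide
exactly) and its large-sample variance come from
`statsmodels.stats.inter_rater.cohens_kappa`; the 95% interval is the
Wald interval point ± 1.96·SE. The CI method behind the published
intervals is unstated, so interval agreement is treated as approximate
(±0.005) rather than exact. Spearman's rho uses average ranks for ties
with a Fisher-z interval. Verbal bands: rho weak < 0.1 / modest / moderate
from 0.31 / strong from 0.51 / very strong > 0.8; kappa poor < 0.2 / fair
from 0.21 / moderate from 0.41 / substantial from 0.61 / almost perfect
from 0.81; MCC very weak from 0.01 / fair from 0.3 / moderately strong
from 0.6 / very strong from 0.8 — lower band edges inclusive.

## Costs

Invoice amounts are nominal euros of their year, converted to base-year
(default 2020) euros by CPI ratio; the shipped German CPI table
(2013–2021) is an editable placeholder config. Categories are disjoint
streams — total-health, BP inpatient, BP outpatient — with BP total
always derived as inpatient + outpatient. Quartiles use linear
interpolation between order statistics (numpy's default, "type 7"); the
Tukey fence Q3 + 1.5·IQR is applied on the upper side only and computed
once per category over the whole analysis cohort, so per-group outlier
percentages share a single fence. Low-cost means *no invoice of that
category* in the window, regardless of amounts. The truncated mean drops
both flag sets; skewness is the adjusted Fisher–Pearson standardised
third moment (`scipy.stats.skew(bias=False)`). Because no quantile rule
or skewness estimator is documented for the original analysis, the
published skew values are treated as qualitative checks only.

## Synthetic data

The generator defines the study conditions:

* grade marginal 42.8/24.7/17.7/14.8% and class-conditional grade rows
  taken from the reported distributions, with the two unprinted cells per
  partially reported row completed proportionally to the grade marginal
  (a neutral, overridable assumption);
* invited fraction 2722/3506; enrolment delay ~ Exp(mean 45 days), so
  ≈ 13% of invitees exceed the 90-day window; 46.1% sick-leave insured;
  3.4% of persons submit no invoices at all;
* the class marginal among invited persons, (0.569, 0.100, 0.331), is
  anchored on the dichotomised table margin (33.1% class 3) with a small
  class-2 share chosen so the severity rate within the non-severe
  prediction matches the reported table. The reported conditional rows,
  grade marginal and table margins are mutually inconsistent at their
  printed rounding, so not all can be matched at once; this
  completion reproduces the reported strength bands (three-level rho
  ≈ 0.38 *moderate*, weighted kappa ≈ 0.32 *fair*) at the expense of a
  grade marginal about three points off at grades I and IV;
* claims are constructed to satisfy the intended class exactly (an
  opioid pair ≤ 183 days apart or a ≥ 42-day attributed episode for class
  3; a 1–41-day episode or ≥ 2 F-diagnoses for class 2; two or more
  back-pain diagnoses for everyone), plus non-qualifying noise (single
  opioid dispensations, single F-diagnoses, non-back-pain sick leave), so
  the classifier round-trip holds for every person and seed;
* questionnaire items are drawn uniformly from the preimage of the
  intended grade under the scorer (rejection sampling over the discrete
  item grid), so the scorer round-trip also holds by construction;
* 12-month cost totals are lognormal per grade and category (σ 0.9–1.0,
  giving raw skew near the reported magnitude), split over 1 + Poisson(2)
  invoices — a deliberate scale-down from the ~27 annual invoices of the
  real setting to keep row counts proportionate. Per-grade means follow
  the reported group means except BP inpatient grades I/II, whose
  reported values are nearly tied in reverse order; the defaults (120,
  180) separate them so group means are strictly ordered by grade, as
  the generator's design requires. Self-selected persons draw their grade
  from the path-specific row; their class is computed from their
  generated claims, never drawn directly.

Randomness flows from one integer seed through named substreams per
record type, so the same seed gives a byte-identical CSV bundle and
adding a record type does not perturb existing draws.

What passing tests on this population do **not** show: the generator has
no temporal disease progression, no correlation between questionnaire
items and costs beyond the shared grade, no realistic billing tariffs,
and conditional independence of class and grade given the configured
rows. Agreement statistics estimated on it validate the *pipeline
arithmetic* (they recover the configured operating point in closed form),
not the real-world validity of the classifier.

## Problem sizes and numerics

The shared test population uses n = 2,000–10,000 persons; the
parameter-recovery and band checks run one n = 100,000 population, where
the multinomial standard error (< 0.5% on each estimated rate) sits well
inside the ±2-percentage-point recovery band. Ties at scoring thresholds
always promote to the upper category; fences and truncation are exact
arithmetic on float64; kappa weighting identities on 2 × 2 tables hold to
float round-off (asserted at relative 1e-12). Degenerate inputs —
empty histories, constant cost vectors, empty margins — return zeros,
NaN sentinels or warnings as documented per function rather than raising
inside simulations.

## Known limitations

The unprinted conditional-row cells and the class-2 share are educated
completions, not ground truth; three-level agreement values produced by
the generator are therefore approximate re-creations. The kappa
confidence interval method is one defensible asymptotic choice among
several. Cost calibration targets group means and qualitative skew, not
the full reported dispersion. Real claims dialects, PHQ-4/comorbidity
scoring and any intervention content are out of scope.
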