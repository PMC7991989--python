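# Methods

## The prediction problem

In a cohort of women managed for gestational diabetes through an mHealth
glucose diary, two trajectories are distinguishable in retrospect: women
managed by lifestyle alone until delivery (*diet–diet*) and women who
transitioned to pharmacological treatment after at least two
medication-free weeks of monitoring (*diet–drug*). The task is a binary
classification of 7-day observation windows: does this week of readings
(plus booking demographics) look like the week preceding a medication
start? A logistic score makes the clinical trade-off explicit — any
operating point on the ROC curve can be chosen — whereas the incumbent
rule (three consecutive raised same-tag readings) is a single fixed point.

## Cohort rules and day arithmetic

All day arithmetic is calendar-day, half-open and 0-based. "First day of
use" is the date of the earliest reading, readings being the only usage
signal in the data model. Eligibility requires gestational (not type 1,
type 2 or MODY) diabetes, complete age and BMI, and at least 36 readings
in `[first_reading, first_reading + 7d)`; exactly 36 qualifies. Exclusion
reasons are assigned with fixed precedence (diabetes type → missing
demographics → sparse readings) so excluded counts are reproducible. A
first medication on day offset ≥ 14 (the 15th day or later) defines
diet–drug; earlier medication excludes the woman (`early_medication`); no
medication at all defines diet–diet. The 36-reading eligibility count uses
all readings; outlier filtering is applied afterwards, before windowing.

## Windows

A window spans exactly 7 days, `[start, start + 7d)`.

* Diet–drug: the canonical window ends one day before the first
  medication date, so the gap day and everything from the medication date
  onward are never observed (first medication on day 20 → window
  `[12, 19)`). If the gap-adjusted window would begin before the first
  reading, the woman is skipped with a warning.
* Diet–diet: candidate weeks are tiled, non-overlapping, from the first
  reading date; a partial trailing week is dropped. Training draws one
  candidate uniformly; validation uses all of them. Drawing the training
  week from the same tiling (rather than arbitrary offsets) keeps the
  training and validation week grids identical.

## Features

Per window: for each meal family (breakfast, lunch, evening meal = pre +
post tag; *all* = every reading) the mean, SD (ddof 1), min, max and the
OLS slope of BG against fractional time-in-days, fitted on raw readings
rather than daily means (more data per fit; the choice only matters for
within-day trends). Per individual tag: mean, min, max. Raised-run counts
for prebreakfast and the three postprandial tags: a calendar day is
"alerted" when any reading of that tag is strictly above the tag's
threshold, and the count is the number of 3-day sliding windows (max 5 in
a week) in which all three days alert; counting overlapping runs keeps the
feature graded rather than binary, and a non-overlapping mode is
available. Plus age, BMI, ethnicity-risk and nine binary risk factors.
Families with fewer than two readings yield missing SD/slope, left to
imputation. A family whose readings all share one timestamp has an
undefined slope (missing).

Alert thresholds are configuration, not learned: defaults are NICE-style
pregnancy targets, 5.3 mmol/L pre-meal and 7.8 mmol/L post-meal. This is
the largest open choice in the design — escalation thresholds vary by
site — so they are exposed per tag in the run config, and any quantitative
statement about the heuristic is conditional on them.

## Preprocessing

The BG outlier cutoff is the empirical 95th percentile
(linear-interpolation definition) of the pooled analyzed readings; values
strictly above are dropped, a value exactly at the cutoff is kept. Only a
high-side cutoff exists — non-positive values are schema violations, not
outliers. Missing feature values are imputed with per-predictor means.
Both fits default to the whole-population convention (`all_population`),
which mirrors how such retrospective analyses are typically run but leaks
a small amount of validation information; `fit_on=train_only` refits the
imputation means inside every repetition on training rows only and is the
recommended mode for honest prospective estimates. The outlier cutoff is
a cohort-level step fitted once, before windowing, in both modes.

## Model

Training rows (one window per training patient) are balanced by randomly
downsampling the majority class to the minority count, without
replacement; validation is never downsampled. Predictors are standardized
to zero mean / unit SD on the training rows; constant predictors pass
through centred. An elastic-net-penalized logistic regression with mixing
parameter α = 0.75 is fitted along a geometric path of 12 penalty
strengths (C from 10⁻²·⁵ to 10¹·⁵, warm-started), and the penalty is
chosen at the minimum of the 5-fold cross-validated deviance; the
one-standard-error rule is available by flag for sparser models. The
predictors with nonzero coefficients are then refitted unpenalized by
maximum likelihood — a two-step use of the penalty purely for selection.
Under complete or quasi-complete separation the unpenalized likelihood
diverges; this is detected (all training rows strictly correctly
classified, or a standardized coefficient above 15) and the fit falls
back to a weak ridge (C = 100), flagged in the model record. The score is
the inverse-logit of the linear predictor, with the stored
standardization reapplied, so scores are invariant to affine rescaling of
any predictor. Fold counts are capped at the minority-class size when the
training set is very small.

## Evaluation

Each of `n_reps` (default 100) repetitions draws a patient-level 70/30
split, stratified by group — no woman ever contributes windows to both
sides, even though diet–diet women contribute several validation
windows. Stratification is used (the alternative, unstratified
permutation, only adds variance). AUC is the Mann–Whitney pair
probability with half-credit ties; the ROC polyline sweeps all distinct
scores so its trapezoidal area equals the pairwise AUC exactly (asserted
in tests). ROC percentile bands are vertical: TPR percentiles (5/50/95)
per point of a fixed FPR grid with 0.01 spacing. Precision–recall curves
are summarized the same way over a recall grid using interpolated
precision (the running maximum from the high-recall end). The clinical
heuristic is evaluated on the same validation windows as the model, so
its (FPR, TPR) point is commensurable with the ROC; the summary reports
the median heuristic point and the model's TPR at that FPR. The
repetition whose AUC is nearest the median is re-examined for per-class
score histograms and its selected feature list. A repetition that raises
is recorded as failed and the run continues. All seeds derive from one
master seed; a full run is bit-reproducible. An empty selection (nothing
survives the penalty) scores every window 0.5 rather than failing the
repetition.

## The synthetic generator

The generator emulates the *structure* such cohorts exhibit, not any real
dataset: one scheduled reading per meal tag per day, dropped independently
with probability `missing_rate`; BG drawn per reading as
tag mean + group shift + patient baseline + noise, truncated at
0.1 mmol/L (positivity is physiologic) and rounded to 0.1 mmol/L
(glucometer resolution); monitoring ends at delivery; diet–drug women
start daily medication events on a day drawn from
`[15, monitoring_days − 7]`, so the 14-day rule is always satisfied
unless excludable patients are requested explicitly.

Default conditions, chosen once on clinical plausibility: 56 monitoring
days with 10% missingness (≈ 300 readings per woman — the right order of
magnitude for monitored GDM cohorts); treated prevalence 39.12%;
pre-meal mean 4.9 and post-meal mean 6.2 mmol/L for diet-managed women,
reading-level SD 0.9; a persistent per-patient baseline with SD
0.6 mmol/L; a constant group shift of 0.8 mmol/L for diet–drug women
applied from day one, plus mild demographic signal (BMI +2 kg/m²,
elevated risk-flag and ethnicity-risk probabilities). The persistent
baseline is essential: without between-woman variation, window averages
would separate the groups almost perfectly at any nonzero shift. Under
these defaults the pipeline's median AUC sits near 0.8 — strong but
imperfect separation, which is the regime the method is meant for.

What the generator does *not* emulate: the post-treatment BG decline
(irrelevant here because every analysis window ends before the first
medication), adherence dynamics and weekday patterns in missingness,
gestational drift in BG, site heterogeneity, and any pharmacokinetics.
Passing tests therefore demonstrate the pipeline's correctness and its
behaviour under controlled signal, not clinical performance on real
cohorts. `generate_null_cohort` forces every group difference to zero
while keeping labels, giving a chance-level (AUC 0.5) calibration
fixture; `generate_excludable_patients` manufactures one patient per
requested eligibility violation.

## Numerical choices and degenerate inputs

Percentile definition: linear interpolation between order statistics.
SDs use ddof 1. Ties in AUC take half credit. The elastic-net solver is
SAGA at tolerance 1e-4 (3000 iterations CV path, 5000 final); the
unpenalized refit is L-BFGS at its default tolerance. Empty meal
families give missing statistics, not errors. An empty cohort yields
zero counts and an explicitly undefined prevalence. Cohort prevalence
percentages are truncated (not rounded) to two decimals, the quoting
convention under which 700/1789 reads 39.12%. Shuffling input row order
changes no cohort verdict (asserted in tests).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run cohorts of 150–600 women
with 5–50 repetitions — sizes at which the calibration properties (null
AUC ≈ 0.5, near-perfect AUC under a 2.0 mmol/L shift at 0.5 mmol/L
noise, monotonicity of AUC in the shift) are stable and the whole suite
stays comfortably reproducible on a laptop.

## Known limitations

* The medication representation is binary; dose and drug class are
  ignored by design.
* The heuristic's thresholds are assumptions, so model-vs-heuristic
  comparisons are qualitative (configurable score dominates fixed rule),
  not site-specific.
* Variable-length windows (2–4 weeks) and time-to-event formulations are
  out of scope.
* `all_population` preprocessing is retained as the default convention
  despite its leakage; switch to `train_only` for prospective claims.
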