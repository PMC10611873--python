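# Methods

This note documents the models and procedures `chronogut` implements,
the choices made where a definition was genuinely open, what the
synthetic cohort does and does not emulate, and the numerical details
that matter for reproducing results.

## Social jetlag and sleep-derived variables

Clock times are stored as integer minutes from midnight. Differences are
computed on an unwrapped axis (a wake time at or before the bed time is
advanced by 24 h) and reduced modulo 24 h afterwards, which avoids both
float drift and wrap-around errors.

- **Mid-sleep point** — the midpoint of the bed→wake interval.
  Sleep duration is time in bed (wake − bed); sleep-latency data are not
  modelled.
- **Social jetlag (SJL)** — weekend mid-sleep minus weekday mid-sleep,
  as the circular representative in (−12, +12] hours. The categorical
  flag uses the 1.5 h cut-off, *inclusive* (exactly 1.5 h counts as
  SJL). Negative SJL (weekday mid-sleep later than weekend) marks the
  record for exclusion; it is never truncated to zero, because negative
  and positive misalignment are different phenomena.
- **Chronotype** — weekend mid-sleep time; later values indicate later
  chronotypes.
- **Habitual sleep duration** — the *unweighted* mean of weekday and
  weekend durations (not a 5:2 weighting); this is the convention that
  reproduces an 8.4 h habitual duration from 8.1 h weekday and 8.7 h
  weekend durations. Categories: short < 7 h, average 7–9 h, long > 9 h.
- **Exclusions**, applied in order with per-rule counts: missing times;
  sleep onset in [08:00, 17:00) (half-open — a deterministic reading of
  "between 8 am and 5 pm"); sleep offset after 12:00 noon (read as
  clock-after-noon, the plainest reading of an ambiguous phrase); time
  in bed < 2 h or > 15 h; negative SJL. Exclusion is idempotent:
  re-running on retained records removes nothing.

## Eating occasions and diet-timing features

An eating occasion (EO) is a chain of logged intake events in which
consecutive events are separated by **less than 30 minutes**; a gap of
exactly 30 minutes splits. The **50 kcal floor applies to the merged
occasion**, not to individual events: sub-threshold events inside a
chain still contribute energy, while an isolated 40 kcal event yields no
occasion. (The alternative — filtering events before chaining — is a
defensible reading; the occasion-level reading matches the definition of
the occasion as the consumption unit.) Occasions are classified main
meal vs snack at ≥ 400 kcal (female) / ≥ 500 kcal (male).

Daily features use occasion *start* times (the log stores instants, not
durations): first/last EO time, eating window (last − first), fasting
window (24 h − eating window; the literal "difference between last and
first occasion" would make fasting identical to the eating window, which
is self-contradictory), and eating midpoint (first + window/2). Days
outside the sex-specific energy range (500–5000 kcal female, 500–8000
kcal male, closed intervals) are dropped. Participant-level features are
means over valid days; clock-time features are averaged on an unwrapped
axis (each time shifted by whole days toward the cohort of values it
belongs with), so midpoints of 23:30 and 00:30 average to 00:00.

## FFQ plausibility and the plant-based diet indices

Energy plausibility uses the original Harris–Benedict coefficients
(male 66.4730 + 13.7516·W + 5.0033·H − 6.7550·A; female
655.0955 + 9.5634·W + 1.8496·H − 4.6756·A; W kg, H cm, A years); records
with energy/BMR outside [0.52, 2.58] or more than ten unanswered items
are excluded.

PDI/hPDI/uPDI: each configured food group is ranked within the cohort
(average ranks under ties, floored into five equal bins → quintile score
1–5, deterministic and order-independent). PDI scores all plant groups
ascending and animal groups reversed (6 − q); hPDI scores healthy-plant
ascending and everything else reversed; uPDI scores less-healthy-plant
ascending and everything else reversed. Indices are sums of group
scores, so their range depends on the number of configured groups (18 by
default here — absolute index values are therefore not comparable to
published cohorts scoring a different group count, but group contrasts
are). HEI and aMED are not implemented: their definitions live in
external scoring software and are not fully specifiable here.

## Postprandial and CGM markers

- **Incremental AUC** — trapezoidal, baseline (t = 0) subtracted, over a
  120 or 360 min horizon. Default mode is `positive_only`
  (Wolever-style): segments are split at their linear baseline crossings
  and only supra-baseline area counts; `net` keeps the signed area. The
  positive-only default is a choice — the trapezoidal-rule citation
  trail does not pin down sub-baseline handling — and the mode is an
  argument everywhere.
- **GlycA 6 h rise** — 6 h value minus fasting value; negative when the
  response dips below fasting.
- **CGM metrics** — readings within 12 h of device fit are discarded
  (sensor calibration); CV = 100·SD/mean with the sample (n−1) SD, the
  CGM-field convention; TIR is the percentage of retained readings in
  the closed interval [3.9, 5.6] mmol/L. Missing readings are simply
  absent; no imputation.

## Differential-abundance screen

Species must be present (relative abundance strictly > 0 — abundance
tables encode absence as exact zero, so no epsilon) in ≥ 20% of **both**
groups. Retained species get a two-sided Mann–Whitney U on raw relative
abundances: exact null distribution when the pooled sample is ≤ 20 and
tie-free, otherwise the tie-corrected normal approximation with
continuity correction. Benjamini–Hochberg correction runs across the
retained family only (filter first, then test). Significance is the dual
criterion q < 0.2 AND |d| > 0.2, with Cohen's d (pooled SD, (n−1)
weights) computed on arcsine-square-root transformed abundances — the
scale the mediation models use — with a raw-scale option
(`d_scale="raw"`). The complementary prevalence-difference screen lists
species prevalent in exactly one group, sorted by |Δprevalence|.

Whole-composition discrimination trains a random forest on all species
over 100 stratified 80/20 train/test splits and reports the median test
ROC AUC; degenerate test splits are redrawn and counted. No class
balancing is applied (a choice; the upstream protocol does not state
one).

## Mediation

Linear product-of-coefficients mediation without exposure–mediator
interaction: mediator model M ~ X + covariates, outcome model
Y ~ X + M + covariates, both with a family random intercept
(`statsmodels` MixedLM, REML) when a cluster column is given, plain OLS
otherwise. Y is the arcsine-square-root transformed relative abundance.
Point estimates: ACME = a·b, ADE = c′, total = c′ + a·b (the
decomposition is exact at the point estimates). Inference is
quasi-Bayesian with n_sims = 1000 by default: fixed-effect vectors drawn
from each model's asymptotic normal, the three effects recomputed per
draw, two-sided p-values as twice the smaller tail mass, 95% intervals
as percentile intervals. Proportion mediated is the **median of
ACME/total over draws**, reported as given — values outside [0, 1] are
flagged, not truncated, and a total effect indistinguishable from zero
flags the ratio as unstable. A cluster-respecting nonparametric
bootstrap (resampling whole families) is available via
`fit(method="bootstrap")`. Categorical covariates are one-hot encoded
against a first-level reference. The reported mediation p-value is the
ACME p-value.

## Covariate-adjusted comparisons

ANCOVA-style: outcome ~ group + covariates (default sex, age, BMI,
ethnicity, education), group coefficient reported. Normality is checked
by Shapiro–Wilk **on the raw outcome** (not residuals — a
residual-based check can be forced by fitting on a pre-transformed
column); if rejected at 0.05, log (positive data) and sqrt (non-negative
data) candidates are tried and the transform maximising Shapiro–Wilk W
wins. BH-FDR is applied per outcome family, with the family boundaries
configurable because published q-value groupings imply per-table
families. Family relatedness can enter as cluster-robust standard
errors on the family ID. The chi-square test for categorical
characteristics uses no Yates correction by default (flag available).

Age matching: controls are restricted to the SJL group's age range
widened by the caliper (2 years by default); SJL participants are
processed in seeded random order, each greedily taking the nearest
remaining control (ties to the younger), without replacement;
participants with no control within the caliper are dropped and listed.
Greedy matching reduces the group age gap on shifted distributions but
is not guaranteed to on adversarial inputs.

Partial correlation is Pearson on double residuals (both variables
residualised on the covariates with intercept), p from t with n − k − 2
degrees of freedom — the `ppcor` convention.

## The synthetic cohort

The generator emulates the structure of a deeply phenotyped ~1000-person
nutrition cohort in which every downstream stage has a planted,
recoverable signal. Defaults are the study conditions: n = 934, 16% SJL
prevalence, SJL group 8.4 y younger and more male (39% vs 25%), nut and
fruit intakes shifted down in SJL (−3.5 and −36 g/day) and
sugar-sweetened beverages, potatoes and fish shifted up (+25.2, +5.3,
+7.2 g/day), six direct-effect species at d = 0.8 on the transformed
scale, two diet-mediated species at proportion mediated 0.15 with nut
intake as the mediator, and a family (twin-pair) random intercept of
SD 0.02 on the transformed-abundance scale for half the cohort.

Key constructions, chosen so the planted coefficients are *exactly* the
generating coefficients:

- **Sleep times**: SJL status is assigned first; mid-sleep points and
  durations are then drawn with the weekday/weekend mid-sleep difference
  kept clear of the 1.5 h boundary (≤ 1.45 h for no-SJL, ≥ 1.55 h for
  SJL), so that re-deriving SJL from the written HH:MM strings
  reproduces the assignment (≥ 99% concordance; in practice 100%).
  Weekend wake times are capped before noon so the exclusion rules stay
  quiet unless records are planted deliberately (`n_negative_sjl`).
- **Food-group intakes** use mean-zero *shifted-gamma* noise at the
  cohort-scale SDs: intakes stay non-negative and right-skewed (as real
  FFQ intakes are) while the SJL shift remains exactly additive in
  expectation, keeping the mediator model correctly specified.
- **Abundances**: null species are log-normal intensities with
  per-species Bernoulli detection (prevalence drawn in [0.10, 0.95],
  creating the ≥ 20%/< 20% structure the screen filters on). Planted
  species are generated directly on the arcsine-sqrt scale
  (z = μ + effects + family intercept + noise, abundance = sin²z) with μ
  in [0.12, 0.20], high enough that the zero-clip is negligible and the
  planted linear model effectively uncensored; planted species have
  detection probability 1 (mediation and effect-size recovery target
  prevalent species). Compositional closure is by a single filler taxon
  absorbing each sample's remainder (rows whose species already exceed
  0.9 are rescaled first — rare at the default scales), so rows sum to
  1 exactly **and** the planted transformed-scale coefficients survive
  closure untouched; per-sample renormalisation would distort them.
  The filler taxon is named `FILLER_remainder` and listed in the ground
  truth so evaluations can account for it.
- **Mediated species**: with a the planted diet shift of the mediator,
  total effect T = −d·σ, the b path is f·T/a and the direct path
  (1−f)·T, so ACME/total is exactly the target proportion mediated f.
- **CGM traces** are a personal baseline (≈ 5.0 mmol/L) plus a diurnal
  oscillation, post-meal excursions at typical meal hours and smoothed
  sensor noise at 15-min cadence; **postprandial series** follow
  gamma-shaped excursion templates on the 10-point 0–360 min protocol
  grid. Both are plausibility-level emulations: they exercise the
  12 h-discard, CV/TIR and iAUC code paths but do not model real
  glycaemic physiology (the synthetic CV ≈ 10% sits below typical
  free-living values).
- All randomness flows from one seed through labelled child generators
  (`SeedSequence` keyed by table name); identical configs give
  bit-identical bundles, and no global random state is touched.

What passing tests show — and do not show. Ground-truth recovery on this
generator demonstrates that the estimators are implemented correctly and
are well calibrated *when their models are correctly specified*
(linear paths, additive family intercepts, monotone group shifts). Real
cohort data add confounding structure, zero-inflation of mediator foods,
compositional coupling among many co-varying taxa, and measurement
error in self-reported sleep — none of which the generator plants, so
recovery here does not certify unbiasedness on real data.

## Problem sizes and runtime choices

The default test suite runs the mediation-recovery protocol at 50
replicates of n = 900 (≈ 1.5 min), the permuted-label screen null at 200
permutations of a 200 × 50 table, and detection checks on three n = 934
cohorts — sizes chosen to keep the whole suite in single-digit minutes
on one CPU while leaving the Monte-Carlo standard errors comfortably
inside the asserted margins. `scripts/acceptance.py` regenerates the
full default cohort (including the ~1.25 M-row CGM table) and runs the
complete pipeline plus the 100-iteration random-forest protocol in
about two minutes.

## Known limitations

- The mediation model assumes sequential ignorability; no sensitivity
  analysis is provided.
- HOMA-IR is consumed as a provided column, never computed (the formula
  variant and inputs are not specifiable from the available
  description); HEI/aMED are likewise out of scope.
- The exact FFQ food-group-to-index mapping of the original scoring
  software is not public; the default 18-group classification is a
  reasonable reconstruction and fully configurable.
- Index values, CGM variability and eating-occasion counts produced by
  the generator match published cohorts in *contrast direction and
  rough magnitude*, not in absolute level.
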