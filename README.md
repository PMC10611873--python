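# chronogut

Analysis pipeline for studying **social jetlag** — the mismatch between
sleep timing on work days and free days — and its associations with
diet, cardiometabolic markers and the gut microbiome in deeply
phenotyped nutrition cohorts.

Social jetlag (SJL) is defined from a sleep questionnaire as the
difference between the weekend and weekday mid-sleep points,
SJL = MS<sub>weekend</sub> − MS<sub>week</sub>, with a categorical
cut-off at ≥ 1.5 h. Starting from participant-level tables (sleep
questionnaire, demographics, time-stamped meal logs, FFQ food-group
intakes, CGM traces, postprandial series, and a species
relative-abundance matrix), the package derives:

- **Sleep**: mid-sleep points, SJL hours and flag, chronotype (weekend
  mid-sleep), habitual sleep duration and short/average/long category,
  with the cohort exclusion rules (daytime onset, afternoon offset,
  implausible duration, negative SJL) applied in order and logged.
- **Chrononutrition**: eating occasions (events chained at < 30 min
  gaps, ≥ 50 kcal per occasion), main-meal/snack classification
  (400/500 kcal by sex), eating and fasting windows, eating midpoint,
  energy-plausibility day filters; plant-based diet indices
  (PDI/hPDI/uPDI) from cohort quintiles; Harris–Benedict-based FFQ
  exclusions.
- **Metabolic markers**: incremental AUC of postprandial curves
  (trapezoidal, baseline-subtracted, positive-only or net), GlycA 6 h
  rise, CGM coefficient of variation and time-in-range (3.9–5.6 mmol/L)
  after a 12 h sensor-calibration discard.
- **Microbiome screen**: species prevalent in ≥ 20% of both groups are
  tested by two-sided Mann–Whitney U with BH-FDR across the retained
  family; significance is the dual criterion q < 0.2 and |Cohen's
  d| > 0.2 (d on arcsine-√ transformed abundances); plus a
  prevalence-difference screen and a 100× bootstrap random-forest
  discrimination protocol (median AUC).
- **Mediation**: how much of the SJL effect on a species runs through
  diet. Linear mediator and outcome models with family random
  intercepts; ACME = a·b, ADE = c′, total = c′ + a·b; quasi-Bayesian
  simulation for CIs and p-values; proportion mediated = median of
  ACME/total over draws.
- **Cohort statistics**: Shapiro–Wilk-guided log/√ transforms,
  ANCOVA-style adjusted group comparisons with per-family BH-FDR,
  SJL × (sex/age/menopause) interaction models with simple effects,
  partial correlations, greedy age matching, χ² tests.

A bundled **synthetic-cohort generator** produces every input table with
planted, recoverable ground truth (SJL prevalence and demographic skew,
diet shifts, direct and diet-mediated species effects, twin-family
random intercepts), so the whole pipeline is testable without any data
access.

## Worked example

```python
import pandas as pd
from chronogut import SyntheticConfig, generate_cohort, derive_sleep
from chronogut.screen import AbundanceTable, screen_species
from chronogut.mediation import MediationSpec, fit_mediation

bundle = generate_cohort(SyntheticConfig(seed=7), include=())

derived, log = derive_sleep(bundle.sleep)
kept = derived[derived.exclusion_reason.isna()]
print(f"{100 * kept.sjl_flag.mean():.1f}% SJL "
      f"(n = {int(kept.sjl_flag.sum())} of {len(kept)})")

labels = pd.Series(bundle.ground_truth["sjl_status"])
res = screen_species(AbundanceTable(bundle.abundance, labels))
print(res.summary())

data = bundle.demographics.merge(bundle.ffq[["participant_id", "nuts"]],
                                 on="participant_id")
data["sjl_flag"] = data.participant_id.map(labels).astype(int)
species = bundle.ground_truth["mediated_species"][0]
data[species] = bundle.abundance[species].reindex(data.participant_id).to_numpy()
med = fit_mediation(data, MediationSpec(
    exposure="sjl_flag", mediator="nuts", outcome=species,
    covariates=["sex", "age", "bmi", "ethnicity", "education"],
    cluster="family_id", seed=7))
print(med.summary())
```

prints

```
18.6% SJL (n = 174 of 934)
Differential-abundance screen
  species tested (prevalence >= 20% in both groups): 92
  significant (q < 0.2 and |d| > 0.2): 10
    up in SJL:   5
    down in SJL: 5
Causal mediation (quasi-Bayesian, 1000 draws, n = 934)
  exposure: sjl_flag   mediator: nuts   outcome: SGB05006
                     estimate                 95% CI        p
  ACME (a*b)          -0.0030 [  -0.0079,    0.0017]   0.1760
  ADE (c')            -0.0269 [  -0.0346,   -0.0192]   0.0000
  Total effect        -0.0299 [  -0.0389,   -0.0203]   0.0000
  Prop. mediated       0.1050 [  -0.0746,    0.2447]
```

The screen recovers the planted differential species; the mediation fit
attributes ≈ 10% of the total SJL→species effect to the nut-intake
pathway (the planted proportion is 15%, inside the simulation interval).

The command line mirrors the library:

```bash
chronogut simulate --n 934 --seed 7 --out cohort/
chronogut report --input-dir cohort/ --output-dir results/ --seed 7
```

writing per-stage CSVs (`sleep_derived.csv`, `participant_features.csv`,
`comparisons.csv`, `screen.csv`, `mediation.csv`), a CONSORT-style
`exclusion_flow.csv`, and a `manifest.json` with the config hash — two
runs with the same config and seed are byte-identical.

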