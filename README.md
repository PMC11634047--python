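# fallrisk

Prognostic-validity analysis of multifactorial fall-risk scores in
residential-care cohorts.

Falls are the leading cause of injury among adults aged 60+ living in nursing
facilities. Multifactorial assessment tools summarise a resident's intrinsic
and extrinsic risk factors (mobility limits, dizziness, medication use,
cognitive impairment, walking-aid use, environmental hazards, ...) into a
single **Fall Risk Score (FRS)** on a 0–100 scale. This package provides the
statistical machinery to ask whether such a score *predicts* future falls —
and what a clinically meaningful change in the score is — from longitudinal
assessment data:

- **Scoring** — FRS = 100 · Σᵢ wᵢ·xᵢ / Σᵢ wᵢ over a configurable factor
  catalog (default: 9 double-weighted + 6 single-weighted factors), with the
  anchors FRS = 0 (no factors) and FRS = 100 (all factors).
- **Cohort handling** — eligibility filtering (age ≥ 60, repeated
  assessments, consistent app version), pairing of consecutive assessments
  (T1, T2) separated by 45–180 days, and normalisation of reported fall
  counts to falls per week: rate = 7 · falls / interval days.
- **Prognostic curve** — a running average of the weekly fall rate per
  integer FRS value (window of 2 FRS points); linear, quadratic
  (a·FRS² + b·FRS + c) and exponential (a·e^{b·FRS} + c) candidate fits;
  selection by lowest RMSE; Spearman rank correlation of the smoothed curve.
- **Thresholds** — inversion of the selected model at
  rate(FRS) · H = 1 expected fall for horizons H = 26 / 52 / 104 weeks,
  rounded up to the next integer percent.
- **MCID** — distribution-based minimal clinically important difference,
  MCID = effect size · SD_pooled with SD_pooled = √((SD²_T1 + SD²_T2)/2) and
  effect sizes 0.2 / 0.5 / 0.8, with percentile-bootstrap 95% CIs.
- **Subgroups** — the whole curve pipeline per stratum (interval bin,
  disease count, age band, gait speed ≷ 0.6 m/s, dementia, fall history,
  walking aids).
- **Synthetic cohorts** — a seeded generator reproducing the target
  population's structure (FRS ~ 29.7 ± 11.8 on [1, 71], intervals
  108.5 ± 31.6 days, Poisson fall counts under a quadratic weekly-rate
  model), so the full pipeline is testable end to end without any data
  download.

## Worked example

Simulate a cohort at the default study scale (617 residents, ~860
observation pairs) and run the full analysis:

```sh
$ fallrisk simulate --seed 11 --out cohort.csv
wrote cohort to cohort.csv
$ fallrisk run cohort.csv --seed 11 --out report
selected model: quadratic (RMSE 0.0182)
spearman rho 0.825 (p 2.9e-16, 61 points)
1 expected fall in 26 weeks: FRS >= 48%
1 expected fall in 52 weeks: FRS >= 31%
1 expected fall in 104 weeks: FRS >= 21%
report bundle written to report
```

The quadratic family wins model selection on this cohort (RMSE 0.018 against
the smoothed curve, lower than linear and exponential), the smoothed
score–rate relationship is strongly monotone (Spearman ρ = 0.83,
p = 2.9×10⁻¹⁶ over 61 smoothed points), and inverting the refitted model
puts the one-expected-fall-in-6-months threshold at FRS 48% for this
realisation. `report/` contains the descriptive table, the smoothed curve,
candidate-model JSON (full-precision coefficients), the subgroup report, the
MCID table and a run manifest recording every decision flag and seed.

The MCID table written by the run (first columns of `report/mcid.tsv`):

```text
effect_size  mcid  ci_low  ci_high
0.2          2.2   2.1     2.3
0.5          5.6   5.3     5.8
0.8          8.9   8.5     9.2
```

i.e. on this cohort an FRS change of ~2 points is a small effect and ~9
points a large one; changes below the small-effect MCID are within
measurement noise.

The reference rate model shipped with the package (the quadratic estimated
on a real German residential-care cohort) can be inverted directly:

```sh
$ fallrisk thresholds
26 weeks: FRS starting at 45%
52 weeks: FRS starting at 32%
104 weeks: FRS starting at 24%
$ fallrisk score --present fall_history,dizziness,foot_disorders
20.83
```

Every subcommand (`score | simulate | run | fit | thresholds | mcid |
subgroups | describe`) is a thin wrapper over the library API
(`fallrisk.compute_frs`, `fallrisk.run_full_analysis`, ...), which is the
recommended interface from Python.

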