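# Methods

## The scientific question

In residential care, fall-prevention assessments are repeated roughly
quarterly. Each assessment produces a multifactorial Fall Risk Score (FRS,
0–100) and a report of falls since the previous assessment. The package
treats each pair of consecutive assessments of the same resident — baseline
T1 and follow-up T2, 45–180 days apart — as one observation, and asks three
questions: does the baseline score predict the fall rate that follows
(prognostic validity); at what score does the expected number of falls over
a clinical horizon reach one (thresholds); and how large must a score change
be to matter (MCID)?

## Scoring model

FRS = 100 · Σ wᵢxᵢ / Σ wᵢ, where xᵢ ∈ {0, 1} flags the presence of factor
*i* and wᵢ is its weight. The default catalog has nine double-weighted
factors (limited mobility, dizziness, visual and auditory impairment,
medication use, cognitive impairment, depression, urge incontinence, fall
history, restlessness — the factors that classical inpatient instruments
such as STRATIFY, Hendrich II and Downton treat as primary) and six
single-weighted factors (mobility-limiting comorbidities, foot disorders,
syncope-causing conditions, fear of falling, walking-aid use, environmental
hazards), total weight 24. Normalising by the maximum attainable weighted
sum is the only definition consistent with both anchors (empty profile → 0,
complete profile → 100) and makes the score invariant to rescaling all
weights by a positive constant. The catalog is a JSON document, so deployed
scores with different factor sets plug in without code changes. "Visual and
auditory impairments" is treated as a single double-weighted factor (keeping
the count of nine). Unknown flags resolve to *absent* with a warning —
the conservative choice, mirroring external assessment fallbacks. Gait
measurements enter through a mapping rule that flags `limited_mobility`
below 0.6 m/s (the slow-walker cut used in the subgroup analyses);
the cutoff is a parameter.

## Fall-rate normalisation

Fall counts reported at T2 cover the T1→T2 interval, whose length varies.
Counts are divided by the interval in days and scaled ×7; the per-week rate
is the analysis unit throughout. Pairing uses consecutive assessments only
(0→1, 1→2, ...): residents contribute one observation per eligible gap, and
non-adjacent combinations are never formed (they would double-count the
intervening interval).

## Running average

Raw per-observation rates are dominated by zeros, so the score–rate
relationship is estimated on a running average: for every distinct integer
FRS value in the data, the mean weekly rate over all observations whose T1
score lies within ±1 point (window of 2 FRS percentage points, closed
interval). The window is *fixed-width* by default; a proportional reading
("2% of the local FRS value") is available behind `adaptive=True` but is not
the default because it degenerates to zero width near FRS 0. Smoothed points
with empty windows are omitted, so every curve point is an average of at
least one observation and inherits non-negativity.

A caveat stated here once: adjacent smoothed points share observations, so
inference computed *on the smoothed points* (the Spearman p-value, the RMSE)
treats autocorrelated quantities as independent. The package reproduces that
procedure deliberately — it is the procedure being validated — and reports
the number of smoothed points alongside, but p-values on smoothed curves
should be read as descriptive.

## Model fitting, selection, thresholds

Linear and quadratic families are fitted by ordinary least squares on the
smoothed points; the exponential a·e^(b·FRS) + c by Levenberg–Marquardt with
initialisation a = rate range, b = 0.01, c = minimum rate and a 20 000
evaluation cap. A non-converging nonlinear fit is returned flagged, never
silently dropped. Selection takes the converged model with the lowest RMSE;
exact ties break toward fewer parameters, then the declared order
linear < quadratic < exponential, and the tie-break is logged. Because
linear is nested in quadratic under the same objective,
RMSE(quadratic) ≤ RMSE(linear) always — a property the tests enforce on
random curves.

Thresholds solve rate(FRS) · H = 1 for horizons H = 26/52/104 weeks (6, 12,
24 months). For the quadratic the positive root is computed in closed form
and rounded *up* to the next integer percent — the "risk starting at"
convention, which reproduces 45/32/24 from the reference coefficients
(a = 2.02977245×10⁻⁵, b = 3.1456122×10⁻⁵, c = −2.34295251×10⁻³); round-up is
the only rounding rule that yields all three published values. If the
expected count never reaches one on [0, 100] a no-threshold signal is
returned. Monotone families fall back to an integer-grid scan.

## MCID

Distribution-based: MCID = effect size × SD_pooled,
SD_pooled = √((SD²_T1 + SD²_T2)/2). The pooled form is symmetric, so equal
dispersions pool to themselves; with the reference dispersions 11.8 and 11.5
it gives 11.651 and MCIDs 2.3/5.8/9.3 at effect sizes 0.2/0.5/0.8. (The
symmetric form is adopted over reading the "/2" as binding only the second
term, which would break symmetry and not reproduce those values.)
Confidence intervals are percentile bootstrap, default 10 000 replicates,
resampling observation rows with the (T1, T2) pair kept together;
`cluster=` switches to resampling whole residents for users who prefer to
respect within-resident correlation. Same seed + same input gives
bit-identical intervals. Sample SDs use the n−1 denominator everywhere;
rounding to one decimal happens only in presentation columns.

## Subgroups

Each built-in scheme maps an observation to one stratum or to `unassigned`
(missing covariate, logged): interval binned to the nearest of 60/90/120
days with half-way ties rounded down (75 d → 60); disease count 0/1/2/3/≥4
over a 15-disease list; age <65, [65, 75), [75, 86), >85 (the published age
bands overlap at their boundaries; these half-open bins are the
implementation's resolution, kept under the original labels); gait speed
≥0.6 vs <0.6 m/s with the boundary in the closed upper bin; dementia;
the two contrasted gait×dementia combinations; fall history; walking-aid
use. Strata whose smoothed curve has fewer than 10 points (configurable) are
reported as `insufficient` rather than fitted. The report cross-checks that
stratum sizes add up to the cohort and tabulates RMSE of the selected model,
Spearman ρ, p, mean (SD) baseline FRS and n per stratum.

## Synthetic cohort generator

The generator emulates the population the analysis is designed for, and its
defaults *are* the study conditions:

| parameter | default | note |
|---|---|---|
| residents | 617 | ~857 observation pairs |
| assessments/resident | 2 w.p. 0.7, 3 w.p. 0.2, 4 w.p. 0.1 | mean 1.4 pairs/resident |
| FRS at T1 | mean 29.7, SD 11.8, integer range [1, 71] | truncated normal, underlying parameters calibrated so the *truncated* moments hit the targets |
| FRS at T2 | mean 29.2, SD 11.5, range [4, 77] | test–retest regression, correlation 0.8 |
| interval | mean 108.5, SD 31.6 d, clipped to [45, 180] | clipping shifts the mean by <0.2 d |
| weekly rate | max(0, a·FRS² + b·FRS + c), reference coefficients | clamp required: a count process cannot have negative mean |
| counts | Poisson(rate · interval/7) | `overdispersion=φ` switches to negative binomial, variance μ(1+φ) |
| covariates | walking aids 622/857, dementia 277/857, fall history 125/857, gait 0.49 ± 0.19 m/s (>0), age 83.3 ± 8.7 (≥60), women 615/857 | sampled per resident |

The T2 score cannot be T1 plus independent drift — the follow-up SD (11.5)
is *smaller* than baseline (11.8), which independent noise cannot produce —
so consecutive scores follow a stationary bivariate-normal regression with
test–retest correlation 0.8 (typical for questionnaire-based instruments;
a config field). Covariates are independent by default except that
walking-aid use is coupled to slow gait (aid probability ~0.85 below
0.6 m/s vs ~0.45 above, preserving the overall 622/857 marginal), matching
the strong association seen in such cohorts. Disease counts follow the
observed 0/1/2/3/≥4 distribution with a 4 + Poisson(0.7) tail.

`generate_profiles` additionally samples raw factor profiles whose computed
scores approximate a target normal via acceptance–rejection (independent
Bernoulli proposal with P = mean/100, accepted against the ratio of target
density to a normal approximation of the proposal's score distribution).
The catalog is a lattice of 100/24-point steps, so the match is approximate;
unreachable targets produce a warning with achieved moments.

What the generator does **not** emulate: informative assessment timing
(intervals independent of risk), score-dependent attrition, covariate–score
dependence beyond the gait/aid coupling, seasonal effects, and reporting
error in fall counts. Passing tests therefore demonstrate that the pipeline
recovers structure the generator contains; they cannot certify behaviour
under real-world missingness or confounding patterns.

## What the large-cohort checks can and cannot recover

On ~200 000 synthetic observations, the smoothed curve's Spearman ρ
exceeds 0.99 and thresholds refitted from the smoothed curve land within
±2 FRS points of the generating 45/32/24. The *leading* quadratic
coefficient is recovered within ~10%. The linear and constant coefficients
are not recoverable to that accuracy by any feasible sample size, for two
structural reasons: (i) the linear term contributes at most b·71 ≈ 2×10⁻³
falls/week — about 2% of the curve's dynamic range — so its estimate is
noise-dominated (sampling SD several times |b| even at n = 50 000); and
(ii) the generating rate is the *clamped* quadratic max(0, q), identically
zero below FRS ≈ 10, so even the infinite-data OLS projection of the true
curve has b and c displaced from the unclamped coefficients (limit relative
errors ≈ −2.4 and −0.6). The test suite states the full three-coefficient
recovery property and the corresponding test fails by design at the b/c
coefficients, documenting the identifiability boundary rather than hiding
it; downstream quantities (thresholds, ρ, model choice) are insensitive to
it because they depend on the curve, not on the coefficient decomposition.

## Numerical and reporting choices

Sizes used by the shipped checks: study-scale runs at 617 residents;
law-of-large-numbers moment checks at 100 000 residents; recovery checks at
~200 000 observations; bootstrap defaults 10 000 replicates (reduced in
smoke tests). Significance level α = 0.05 is recorded in the run manifest,
as are the window mode, rounding and tie-break rules, bootstrap unit and
seeds; rerunning with an identical manifest reproduces every output file
byte for byte. Degenerate inputs are first-class: constant smoothed curves
yield a flagged degenerate correlation (not NaN), single-observation MCIDs
collapse with a warning, zero eligible pairs terminate with a dedicated
signal and CLI exit code 3.

## Known limitations

- The Spearman p-values on smoothed points inherit window-overlap
  autocorrelation (see above).
- The threshold inversion assumes a convex quadratic on the observed range;
  models selected from other families use a grid scan and integer precision.
- The factor catalog defaults capture the published weighting scheme but not
  any proprietary calibration a deployed score may add.
- Bootstrap CIs are percentile-method; no BCa correction (skewness of the
  pooled-SD statistic at these sample sizes is negligible relative to the
  reported precision).
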