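# Methods

## Scores

qSOFA sums three indicators — systolic blood pressure ≤ 100 mmHg,
respiratory rate ≥ 22/min, altered mentation — with both numeric thresholds
inclusive. MqSOFA adds 0/1/2 points for the SpO2/FiO2 (S/F) ratio, computed
with SpO2 on the percent scale and FiO2 as a fraction in [0.21, 1.0] (room
air = 0.21; no oxygen-flow-to-FiO2 conversion is attempted, and an
`intubated` flag causes record exclusion rather than scoring). Bands are
defined on the real line with no pre-rounding of the ratio: ≤ 235 → 2
points, (235, 315] → 1, > 315 → 0.

The published definitions disagree at exactly S/F = 315: the point table
assigns 0 only from 316 up, the prose from 315 up. The package defaults to
the point-table reading (315 scores 1 point), which keeps S/F = 315 on the
abnormal side exactly where it maps to the P/F = 300 boundary under the
conversion log10(P/F) = 0.48 + 0.78·log10(S/F) (base-10 logarithms, the
source regression's convention). The alternative reading is available as
the `text` dialect everywhere a score is computed; the conflict is
deliberately explicit and testable rather than silently resolved. Which
reading the original study used cannot be determined, and only ratios
landing exactly on 315 are affected.

"Altered mentation" is accepted as a boolean; no GCS or AVPU
operationalization is imposed because none is defined for the score.

Risk groups at cutoff 2: low (qSOFA < 2 and MqSOFA < 2), reclassified high
(qSOFA < 2, MqSOFA ≥ 2), high (both ≥ 2). The fourth combination is
unrepresentable since MqSOFA ≥ qSOFA, and the code treats it as an
invariant violation, not a fourth category.

## Cohort I/O

CSV, comma-separated, UTF-8, header required; booleans accepted as
true/false, 1/0, yes/no (case-insensitive); sex strictly M/F. Missing-data
policy is listwise exclusion with per-reason tallies (`missing_field`,
`invalid_value`, `intubated`); imputation is never attempted. The reason
taxonomy is the package's own — the source cohort's 1137 → 1001 attrition
is not broken down by field. Ages are accepted in [18, 120], wider than the
validation cohort's observed 19–99, so plausible records are not silently
dropped. Exclusion accounting (input = retained + Σ reasons) is asserted on
every read.

The packaged joint table (`table2_fixture`) carries the published 6×4
MqSOFA-by-qSOFA counts with grand total 1001 and column totals
278/334/254/135; its empty upper triangle and margin consistency are
validated on construction.

## Synthetic cohort generator

The generator's defaults are the published study conditions; it exists so
that every downstream stage can run and be tested without the original
(non-public) patient data.

**Scores.** `exact` mode enumerates each cell of the joint table
(optionally scaled by an integer factor); `sampled` mode draws one
multinomial of size n over the cell frequencies. In exact mode the
tabulated cohort equals the input table for every seed, by construction.

**Mortality.** Death is Bernoulli with
p(death | MqSOFA = m) = expit(α + β₁·m), β₁ = ln 2.38 (the published
per-unit odds ratio). The intercept α is solved by bisection on [−20, 20]
so the table-weighted mean death probability equals 333/1001 to 1e-10. The
published data never report deaths per score cell, so any mortality surface
matching the printed margins is admissible; logistic-in-MqSOFA (with no
extra qSOFA term) is the simplest such surface and makes the logistic
parameter-recovery tests exact in expectation. An optional age coefficient
(default ln 1.03 per year when enabled) switches the generator to drawing
age first from the marginal cohort normal (79.4 ± 12.9) and death from
expit(α + β₁·m + β_age·(age − 79.4)), with α recalibrated by Gauss–Legendre
quadrature over the truncated age density.

**Vitals.** Given an assigned (qSOFA, S/F points) cell, the qSOFA points
are placed uniformly at random over the three items; SBP is uniform on
(70, 100] with the point and (100, 160] without, RR uniform on [22, 40) /
[10, 21). These windows are invented plausibility ranges — their only
obligation is to respect the score thresholds. The S/F ratio is uniform
within the assigned band ([100, 235], (235, 315], (315, 470]), shrunk by a
1e-3 interior margin at the 235/315 edges so the SpO2 = ratio·FiO2 →
SpO2/FiO2 float round-trip can never flip a band; FiO2 is then uniform on
the feasible interval keeping SpO2 in [60, 100], which is nonempty for
every in-band ratio.

**Demographics and stay.** Default mode draws age conditional on outcome
(died 82.4 ± 10.7, discharged 77.9 ± 13.6, truncated to [18, 110] by
inverse-CDF), matching the only printed age summaries — a generative
convenience, not a causal claim. Sex is Bernoulli(462/1001). Survivor
length of stay is log-normal per risk group with μ = ln(median) and
σ = (ln q3 − ln q1)/(2 × 0.67449), reproducing the printed medians/IQRs
8.5 [6–13], 10 [6–13], 10 [7–14] days; a degenerate IQR gives σ = 0.
Non-survivor stay is unreported in the source, so it is a free parameter:
exponential with mean 7 days truncated to [1, 60] (inverse-CDF sampled).

All draws come from one seeded PCG64 generator in a fixed per-patient order
(item assignment, SBP, RR, ratio, FiO2, death, age, sex, LOS), so a seed
determines the cohort byte for byte within this implementation.

**What the generator does not emulate:** multivariate physiology (vitals
are conditionally independent given the score cell), comorbidity, any
qSOFA-given-MqSOFA or sex/seasonal mortality structure, time-varying
vitals, and the survival-time *shapes* behind the published Kaplan–Meier
curves. Consequently, passing tests demonstrate that the pipeline recovers
programmed parameters and printed margins — not that MqSOFA performs as
published on new clinical data. In particular the published log-rank
p = 0.551 (high vs reclassified) and LOS p = 0.009 depend on unpublished
patient-level times and are reproduced only qualitatively (direction and
ordering), never asserted numerically.

## Diagnostics

Positivity is score ≥ 2, condition-positive is in-hospital death.
Percent reporting rounds half away from zero to 1 decimal, with raw
proportions always retained; undefined metrics (zero margin) are explicit
`None`, never silent zeros. `reconstruct_confusion` rebuilds integer 2×2
cells from printed sensitivity/specificity and the 333/668 margins with
round-half-up; the reconstruction reproduces every printed accuracy, PPV,
NPV and dichotomized OR except the qSOFA PPV, where no integer table
consistent with the printed sensitivity/specificity/margins yields 52.1% —
the reconstruction gives 52.2%, and the package surfaces this as a
documented discrepancy rather than forcing a match. Odds-ratio intervals
are Wald on the log scale (the source does not name its CI method); zero
cells get the 0.5 continuity correction, flagged in the result.

## Discrimination and regression

The ROC AUC uses the Mann–Whitney kernel with half-credit for ties —
required for ordinal 0–5 scores — and is computed as a single division of
an exactly representable sum of halves, so it matches brute-force pair
counting bit for bit. Variance and the paired two-score comparison follow
DeLong's placement-value construction with sample variances (n−1 divisor);
the comparison z uses var_A + var_B − 2·cov of the paired placements. The
source does not name its AUC-comparison method; DeLong is chosen as the
standard for correlated ROC curves on a paired design. CIs are Wald on the
AUC scale clamped to [0, 1].

Logistic regression is Newton–Raphson from the zero vector, convergence
when the largest coefficient update is below 1e-8, at most 25 iterations;
Wald standard errors from the inverse observed information; any |β| > 15
during iteration raises a separation error. The age-adjusted model is
score + age only — whether the published multivariate model held further
covariates is not stated, so none are invented.

Hosmer–Lemeshow uses g = 10 equal-count bins by sorted fitted probability,
with tied probabilities kept in one bin (so ordinal scores yield at most
one bin per distinct fitted value) and df = bins − 2. Calibration claims in
the test-suite are stated only as rejection rates on synthetic nulls.

## Survival and length of stay

Time is days in hospital; death is the event and discharge alive censors.
At tied times deaths are processed before censorings (standard
product-limit convention). The k-group log-rank accumulates hypergeometric
observed/expected counts per event time and uses a generalized inverse of
the (k−1)-dimensional variance block. Length of stay is analysed in
survivors only: quartiles by linear interpolation between order statistics
(the printed "IQR: 6–13" style depends on the quartile rule, so it is
fixed and documented), Mann–Whitney for two groups and tie-corrected
Kruskal–Wallis for three. The Mann–Whitney U is oriented so that
U/(n_A·n_B) equals the probability-of-superiority of the second group —
the same functional the ROC AUC estimates, which the tests exploit as a
cross-module identity. All p-values are two-sided; 0.05 is the reporting
threshold.

## Numerical choices and problem sizes

Calibration tolerance 1e-10 on the marginal mortality; logistic tolerance
1e-8/25 iterations, deterministic zero initialization; AUC/U identities
asserted to 1e-12; percent reporting to 1 decimal, ORs to 2, AUCs to 3.
Convergence-style checks run on exact-mode cohorts at 20× the packaged
table (n = 20 020) — large enough that 3-standard-error recovery bands are
tight, small enough to keep the suite fast; null-calibration checks use 500
replicates at n = 400 (Hosmer–Lemeshow), 60 per group (log-rank) and 30 per
group (Kruskal–Wallis), sizes at which the chi-square approximations are
expected to hold. The paired-ROC power check uses 100 seeds at the study's
own n = 1001.

## Known limitations

* The mortality surface, non-survivor stay distribution and vitals windows
  are modelling choices constrained only by printed margins; cohorts are
  realistic in their summaries, not in patient-level joint structure.
* The S/F = 315 dialect ambiguity is unresolvable from the source; results
  are insensitive except for ratios exactly on the boundary.
* Wald intervals (OR, AUC) can misbehave near boundary estimates; the
  bootstrap exists in the test suite as an oracle, not as a user-facing
  alternative.
* The Hosmer–Lemeshow test on few distinct ordinal risks has reduced
  degrees of freedom and correspondingly low power.
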