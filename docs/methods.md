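# Methods

## Indices

All index computations are pure, seed-free, double precision. Glucose is
mmol/L, insulin mIE/L throughout; a configuration constant
(`indices.MGDL_PER_MMOL = 18.0182`) is provided for users converting mg/dL
data. With this units convention the Matsuda composite index

    ISI = 10000 / sqrt(G0 · I0 · Gmean · Imean)

lands on the scale on which population tertile boundaries fall near 78 and
133; the mg/dL convention of the original composite index yields values
about 18× smaller and would require rescaling every threshold.

Mean glucose and mean insulin are unweighted arithmetic means of exactly the
0-, 30-, 60- and 120-min samples. A 90-min sample is accepted in the input
schema and ignored; no trapezoidal weighting is applied.

The corrected insulin response uses the mmol/L variant

    CIR = 100 · I30 / (G30 · (G30 − 3.89)),

with the 3.89 mmol/L (70 mg/dL) offset configurable
(`glucose_offset` argument). When `G30 ≤ 3.89` the denominator is
non-positive and CIR is flagged undefined (NaN) rather than returned as a
negative secretion index; such subjects keep ISI but drop out of DIo
analyses, and the count is logged. The oral disposition index is the exact
product `DIo = CIR × ISI`.

Missing-data policy is complete-case per derived quantity: a subject missing
I30 loses CIR and DIo but keeps ISI whenever all four ISI inputs are
present. `compute_indices` is row-wise independent — one subject's missing
sample never affects another's indices.

## Exclusions and classification

Subjects with fasting glucose ≥ 7.0 mmol/L are treated as having diabetes
and excluded before analysis; a diabetes-medication flag column, when
present, also excludes. A missing fasting glucose excludes with its own
logged reason. The filter is idempotent.

Weight classes are BMI < 25 (normal weight), [25, 30) (overweight),
≥ 30 (obesity); no underweight category is used. Abdominal obesity is
waist ≥ 94 cm in men and ≥ 80 cm in women (WHO/IDF).

Tertile boundaries are the 1/3 and 2/3 quantiles of the *reference*
population's ISI, interpolated linearly between order statistics at
positions `p·(n−1)+1` (numpy's default rule; a nearest-rank option exists).
Classification applies the raw (unrounded) cuts with strict "<" below the
first boundary and "≥" at the upper ones, so a reference sample of size 3k
without boundary ties splits exactly k/k/k; boundaries are rounded half-up
to one decimal for reporting only. Ties at a boundary follow the
inequalities and are never split. Percentages in prevalence tables are
rounded half-up to one decimal.

## Equivalence cut-offs

The question: at which BMI (waist) does the comparison group attain the
age-adjusted log10 ISI (or log10 DIo) that the reference group has at a
standard threshold?

1. **Age adjustment.** log10-transform (the outcome distributions are
   right-skewed), then residualize on age by least squares and add back the
   sample mean. Adjustment is pooled across groups within sex by default
   (one age slope per sex); a per-group switch exists
   (`CutoffConfig.age_adjust`). Pooling was chosen because a common age
   slope keeps the two groups' adjusted levels on one comparable scale; the
   per-group option lets users probe sensitivity. With zero age variance
   the adjustment is skipped under a warning.
2. **Line fits.** Ordinary least squares of the adjusted outcome on the
   measure within each group × sex. A straight line is the functional form:
   it is the minimal model under which "the same level" has a unique
   crossing point, and the reported residual SD lets users judge fit. No
   smoother is fitted by default.
3. **Solve.** `x_cmp = (a_ref + b_ref·x_ref − a_cmp) / b_cmp` at thresholds
   BMI 25 and 30 kg/m² and waist 94 cm (men) / 80 cm (women). When the two
   fits are bitwise identical the threshold itself is returned, making the
   self-comparison identity exact in floating point. A comparison slope
   below 1e-8 in absolute value raises a non-identifiability error. Raw
   solutions are always reported; a reporting grid (0.5 kg/m² BMI, 1 cm
   waist) matches the resolution at which such cut-offs are usually quoted.
   Solutions outside the comparison group's observed measure range are
   flagged as extrapolated, not suppressed.
4. **Uncertainty.** Optional percentile bootstrap: subjects are resampled
   with replacement within each group, the age adjustment and both fits are
   recomputed per resample (default 1000 resamples in the config; a seed is
   mandatory). Strata below `min_n` (default 30) subjects are marked
   unreliable.

## Risk-factor regression

Multivariate OLS of log10 ISI on a declared term list. Continuous
predictors are divided by their sample SD (denominator n−1, no centering),
so coefficients read "per 1 SD"; binary indicators stay unstandardized.
Inference uses classical SEs with normal-approximation 95% CIs and
two-sided p-values (t-based by option), significance at 0.05. Right-skewed
inputs (default list: ISI, DIo, triglycerides) are log10-transformed by
`log_transform_policy`, with provenance recorded.

VIF per term is `1/(1−R²)` from regressing that term on the others; a value
at or above 3.5 triggers a warning, and perfect collinearity reports an
infinite VIF. A rank-deficient design raises an error listing the collinear
terms.

Interaction testing is gated to limit the multiple-testing burden: a
term × moderator product is fitted and tested only when the term's marginal
effect in the base model is significant at 0.05; gated terms are reported
as "skipped (gated)".

Age-adjusted two-group comparisons use OLS (difference in means) or
logistic regression via Newton iterations (odds ratio for proportions; max
50 iterations, tolerance 1e-8), each on group + age. Complete separation
surfaces as a convergence error.

Because published stratified tables rarely document their model-building
path, the package fits the declared term list and reports every term; an
optional backward-elimination mode (drop the least significant term with
p ≥ 0.05, one at a time) emulates tables in which non-significant cells are
blank. Missing covariates are handled complete-case per model with n
reported; no imputation.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, per
group × sex stratum: truncated-normal age on [30, 75] (rejection
sampling), normal BMI, waist linear in BMI plus noise, and a latent
log10 ISI that is linear in BMI and age with Gaussian residual (log-normal
ISI noise, matching the pipeline's log10 rationale). Glucose trajectories
are a positive 5-point template with multiplicative log-normal noise; the
90-min sample is generated but carries no information, so the "ignore
90 min" rule is exercised.

Insulin is the response shape (1, a, 4, 3)·s at 0/30/60/120 min
(3.5·s at 90 min). The scale `s` is solved in closed form so that the
Matsuda formula applied to the generated trajectory returns the latent ISI
exactly — the exact-inversion contract that makes planted effects
recoverable to machine precision. The 30-min peak factor `a` is a separate
per-subject beta-cell term (log-normal around 5, with its own negative BMI
loading −0.015 log10 per kg/m²): without it CIR would be a deterministic
function of ISI and the DIo analyses would degenerate. Triglycerides
(negative loading) and HDL (positive loading) are linked to the latent
log10 ISI; smoking and family history are Bernoulli; physical activity is
truncated normal.

Default effect sizes: ISI–BMI slope −0.035 log10 per kg/m² with residual
SD 0.20 on the log10 scale (a BMI–log10 ISI correlation around −0.6, in
the range OGTT cohort studies report), age slope −0.004 per year, BMI SD
4.5 kg/m² in the stylized scenarios.

Scenarios:

- `realistic` — group- and sex-specific parameters calibrated to the
  magnitudes published for adult European-origin (reference) and
  Middle-Eastern-origin (comparison) OGTT cohorts: stratum sizes
  326/362/493/683, ages 44–50 (SD 9–11), BMI means 26.8–29.4, target
  median ISI 111.4 / 90.1 / 90.5 / 70.1. Intercepts are back-computed from
  the target medians, so simulated stratum medians land within a few
  percent of the targets and the reference tertile boundaries emerge near
  78/133 without being planted.
- `null` — both groups share the reference parameters (exchangeable).
- `shift` — like `null`, but the comparison group's ISI–BMI line is
  displaced horizontally by Δ kg/m², so the true equivalent of a reference
  threshold x is exactly x − Δ.

All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn`, one substream per stratum in sorted
stratum order, so identical parameters and seed give bit-identical cohorts
and resizing one stratum does not disturb another's draws.

What the generator does **not** emulate: physiological (minimal-model)
glucose–insulin dynamics, assay error, non-linear ISI–adiposity relations,
missing data, and migration-duration effects. Passing tests therefore
demonstrate that the *estimators* recover planted structure under the
stated model — not that real cohorts satisfy that model.

## Calibration experiments and problem sizes

- Planted-shift recovery: Δ ∈ {1, 2, 4} kg/m², 2000 subjects per group and
  sex, 20 seeds; mean absolute error of the recovered BMI cut-off at the
  obesity threshold stays below 0.2 kg/m² (its analytic sampling SE there
  is ≈ 0.15–0.19). Waist cut-offs inherit a weaker, induced slope (ISI
  loads on BMI; waist correlates with BMI) and carry a sampling SE near
  0.6 cm at the same n.
- Bootstrap coverage: 200 resamples, 50 seeds, 500 subjects per group;
  percentile CIs cover the planted cut-off in ≥ 90% of seeds at nominal
  95%.
- Interaction-scan calibration: the null design plants marginal effects
  0.4/0.3/−0.25/−0.3 with residual SD 0.5 (chosen by power analysis so a
  standardized interaction of 0.1 at n = 1500 is detectable with ≥ 80%
  power; type-I error is measured at n = 800 over 500 seeds and sits in
  [3%, 7%] at α = 0.05).

## Numerical choices and degenerate inputs

- Quantiles: linear interpolation between order statistics (configurable to
  nearest rank); degenerate references (< 3 values, or all equal) error.
- Percentage and boundary rounding: decimal half-up (not banker's), one
  decimal.
- Equivalence solver: slope tolerance 1e-8; identical fits short-circuit to
  the exact threshold.
- OLS: rank checked before fitting; rank-deficient designs error listing
  the collinear terms rather than silently dropping one.
- Logistic fits: Newton, max 50 iterations, deviance tolerance 1e-8;
  separation raises.
- CSV export uses `%.17g` floats so write → read round-trips every double
  exactly; the reader detects malformed numerics per row (rejecting only
  the offending rows) and parses values with correctly rounded strtod.

## Known limitations

- Cross-sectional logic only: an equivalence cut-off is a descriptive
  crossing point of two regression lines, not a prospective risk threshold.
- Linearity of adjusted log10 outcome in BMI/waist is assumed, not tested;
  residual SD and the extrapolation flag are the only diagnostics provided.
- The published headline cut-offs and prevalences of any specific study
  depend on its cohort; without those data this package can only verify
  the machinery (closed forms, worked-example percentages from printed
  counts, planted-parameter recovery), not reproduce cohort-specific
  estimates.
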