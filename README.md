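# ogttools

Analysis pipeline for oral glucose tolerance test (OGTT) cohort studies that
compare insulin sensitivity between two populations — for example a migrant
population at high risk of type 2 diabetes versus the native population of
the host country. Standard obesity thresholds (BMI 30 kg/m², waist 94/80 cm)
were derived in European populations; in populations with different fat
distribution the same metabolic risk appears at lower BMI and waist values.
This package computes OGTT-derived insulin sensitivity and secretion
indices, classifies insulin resistance against a reference population's
tertiles, and — its core — solves for the group-specific BMI and
waist-circumference values at which a comparison population has the *same*
age-adjusted insulin sensitivity as the reference population at its standard
thresholds.

Intended users: epidemiologists and biostatisticians analysing per-subject
cohort tables with OGTT sampling at 0/30/60/(90)/120 min.

## Methods in brief

Per subject, with glucose `G_t` in mmol/L and insulin `I_t` in mIE/L:

- mean glucose/insulin: arithmetic mean over 0, 30, 60 and 120 min
  (a 90-min sample, if drawn, is ignored);
- **ISI** (Matsuda composite index):
  `ISI = 10000 / sqrt(G_0 · I_0 · G_mean · I_mean)`;
- **CIR** (corrected insulin response, beta-cell secretion):
  `CIR = 100 · I_30 / (G_30 · (G_30 − 3.89))`, undefined when
  `G_30 ≤ 3.89 mmol/L`;
- **DIo** (oral disposition index): `DIo = CIR × ISI`.

Subjects with fasting glucose ≥ 7.0 mmol/L (or on diabetes medication) are
excluded. The reference population's ISI distribution is cut at its 1/3 and
2/3 quantiles; everyone below the first boundary is "insulin resistant",
at/above the second "insulin sensitive", in between "intermediate".

For the equivalence cut-offs, log10 ISI (or log10 DIo) is age-adjusted by
least-squares residualization (pooled across groups within sex, mean added
back), an OLS line of the adjusted outcome on BMI (or waist) is fitted per
group, and the comparison-group cut-off solves

```
x_cmp = (a_ref + b_ref · x_ref − a_cmp) / b_cmp
```

at the reference thresholds (BMI 25 and 30 kg/m²; waist 94 cm men / 80 cm
women). A percentile bootstrap (resampling subjects within group) gives CIs.
Risk-factor models are multivariate OLS on log10 ISI with continuous
predictors standardized to unit variance ("per 1 SD"), VIF screening
(warning at ≥ 3.5), and moderator-interaction tests gated on significant
marginal effects.

A seeded synthetic-cohort generator produces two-group × two-sex cohorts
whose OGTT trajectories invert the Matsuda formula exactly, so the full
pipeline is testable end to end without access to a real cohort. See
`docs/methods.md` for model assumptions and parameter choices.

## Worked example

```python
import ogttools as og

# two exchangeable populations except that the comparison group's ISI–BMI
# line is displaced by 2 kg/m² (its true equivalent of BMI 30 is 28.0)
params = og.default_params("shift", seed=7, n=2000, delta=2.0)
cohort = og.generate_cohort(params)
cohort, excluded = og.exclude_diabetes(cohort)
indices = og.compute_indices(cohort)

ref = og.tertile_reference(indices.loc[cohort["group"] == "reference", "isi"])
print(f"ISI tertile boundaries (reference group): {ref.rounded()}")

results, _ = og.run_cutoff_analysis(cohort, indices, "reference")
for r in results:
    if r.measure == "bmi" and r.outcome == "log10_isi" and r.reference_threshold == 30.0:
        print(f"{r.sex}: BMI cut-off equivalent to reference BMI 30 -> "
              f"{r.cutoff_raw:.2f} (rounded {r.cutoff_rounded})")
```

prints

```
ISI tertile boundaries (reference group): (84.3, 141.0)
female: BMI cut-off equivalent to reference BMI 30 -> 28.10 (rounded 28.0)
male: BMI cut-off equivalent to reference BMI 30 -> 27.68 (rounded 27.5)
```

The tertile boundaries are the simulated reference population's ISI cuts
(insulin resistance = ISI below the lower one). The recovered cut-offs sit
within sampling error of the planted 28.0: a comparison-group subject at
BMI ≈ 28 has the age-adjusted insulin sensitivity of a reference-group
subject at BMI 30. Cut-offs are reported raw and snapped to a 0.5 kg/m²
(BMI) or 1 cm (waist) grid.

The same pipeline runs from a shell:

```
ogttools simulate --scenario shift --delta 2.0 --n 2000 --seed 7 --out cohort.csv
ogttools indices  --in cohort.csv --out indices.csv
ogttools classify --in cohort.csv --indices indices.csv --out prevalence.csv
ogttools cutoffs  --in cohort.csv --indices indices.csv --out cutoffs.csv
ogttools report   --seed 7 --out results/
```

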