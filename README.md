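# ghdpretest

Pre-test probability modelling for adult growth-hormone deficiency (GHD).

GHD in adults is confirmed by stimulation tests — the insulin tolerance
test (ITT) and the GHRH + arginine test — whose sensitivity and specificity
are good but not perfect. Interpreting a single blunted or normal GH
response without knowing how likely the patient was to have GHD in the
first place invites false positives and false negatives. This package is
for endocrinologists and biostatisticians who want that prior quantified
and propagated: it implements a published two-predictor logistic model of
pre-test GHD probability, the class-imbalance-corrected procedure used to
develop such a model, its internal validation, and the Bayesian update that
combines the prior with a test result.

## The model

For a patient with IGF-I standard-deviation score `S` (age-referenced) and
other-pituitary-deficit indicator `D` (1 = any non-GH axis deficient):

```
P(GHD) = e^z / (1 + e^z),   z = 1.82·D − 1.27·S − 1.77
```

Inverting the model at a target probability q gives the IGF-I SDS cut-off
`S*(q, D) = (logit(q) − β₀ − β_D·D) / β_S`, which yields the risk-class
table (low < 25%, high > 75%):

| P(GHD) | cut-off, no other deficits | cut-off, other deficits |
|-------:|---------------------------:|------------------------:|
| 25%    | −0.53                      | +0.90                   |
| 50%    | −1.39                      | +0.04                   |
| 75%    | −2.26                      | −0.83                   |

A test result then updates the prior by Bayes' theorem; at the working
sensitivity/specificity of 0.90 a prior of 25% maps to exactly 75% after a
deficient response, so a low-risk patient can never be confirmed — and a
high-risk patient never excluded — by one test alone, which is the
rationale for the second-test recommendation logic.

Model development mirrors the original procedure: the majority class is
randomly undersampled to a 1:1 ratio, the two-predictor logistic model is
fitted by from-scratch IRLS on the balanced subset, the step is iterated
ten times and the coefficient vectors averaged on the log-odds scale, with
Hosmer–Lemeshow calibration per iteration, apparent ROC AUC on the
original cohort, and stratified ten-fold cross-validation of the entire
procedure.

## Worked example

The raw study cohort is not public, so the package ships a generator with
the study population's statistical structure (80 patients, 54 GHD / 26
normal, group-conditional IGF-I SDS and deficit prevalence):

```
$ ghd-pretest simulate --n 80 --seed 7 -o cohort.csv
$ ghd-pretest fit -i cohort.csv --seed 7 -o model.json
averaged coefficients: intercept -2.278, igf_i_sds -1.606, other_deficits +2.321; apparent AUC 0.826
$ ghd-pretest validate -i cohort.csv --seed 7 -o cv.json
cross-validated mean AUC 0.827
```

The averaged coefficients are this synthetic cohort's analogue of the
published (−1.77, −1.27, +1.82): negative in IGF-I SDS (lower IGF-I, higher
risk), positive for other deficits, with sampling noise appropriate to
n = 80. The apparent AUC is the averaged model's discrimination on the full
unbalanced cohort; the cross-validated AUC estimates performance on unseen
data, and their closeness indicates negligible overfitting for a
two-parameter model.

Interpreting a test result for a low-risk patient:

```
$ ghd-pretest bayes --pre 0.12 --result deficient
{
  "decision": "second_test_advised",
  "post_test_probability": 0.5510204081632654,
  "pre_test_probability": 0.12,
  "rationale": "low pre-test probability with a deficient GH response: a single
                positive test cannot confirm GHD; a second stimulation test is advised"
}
```

A deficient response moved this patient from 12% to 55% — informative, but
not confirmatory, hence the second test. `ghd-pretest cutoffs`,
`predict` and `classify` cover the cut-off table, batch scoring, and
BMI-stratified GH-response/concordance classification; everything is also
available as library functions (`ghdpretest.predict_probability`,
`fit_averaged_model`, `post_test_probability`, ...).

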