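# Methods

## The clinical problem

Adult growth-hormone deficiency (GHD) is diagnosed by a subnormal peak GH
response to stimulation tests — here the insulin tolerance test (ITT) and
the GHRH + arginine (GHRH+ARG) test — interpreted against BMI-stratified
cut-offs. Neither test is perfectly accurate (literature sensitivity
87–96%, specificity 79–92%), so a single blunted or normal response can
mislead. This package implements a pre-test probability model that
quantifies GHD risk *before* testing from two cheap predictors — the
age-referenced IGF-I standard-deviation score (SDS) and the presence of any
other pituitary-axis deficit — together with the imbalance-corrected
procedure used to develop it, its internal validation, and the Bayesian
machinery for combining the pre-test probability with a test result.

## Clinical layer (`ghdpretest.clinical`)

IGF-I SDS is `(observed − age-specific reference mean) / age-specific
reference SD`, with the reference supplied by the user as a table of
half-open `[age_min, age_max)` brackets. No default normative table is
bundled: the original score used a published reference for healthy Italian
adults whose bracket values are not reproducible here, so ages outside the
supplied coverage raise an error rather than extrapolate. When a record
carries both a pre-computed SDS and the raw-value route, the supplied SDS
wins and a warning is logged.

BMI classes are lean (< 25 kg/m²), overweight ([25, 30)), obese (≥ 30),
closed on the left. Peak GH thresholds are 11.0 / 8.0 / 4.0 µg/l
(GHRH+ARG) and 3.5 / 1.3 / 1.3 µg/l (ITT) for lean / overweight / obese; a
response is *normal* only when the peak strictly exceeds the threshold, so
a peak exactly at the threshold is deficient. Two concordantly deficient
tests define GHD, two concordantly normal tests define normal somatotroph
function, and discordant pairs are excluded from model development.
Antidiuretic-hormone deficiency counts toward the "other pituitary
deficits" flag like any other non-GH axis.

## Logistic engine (`ghdpretest.logit`)

The binary logistic MLE is computed by iteratively reweighted least squares
(Newton scoring), written in-house because the fitting procedure and its
failure modes are part of what this package is for; statsmodels and
scikit-learn serve only as independent cross-checks in the test suite.
Convergence is declared when the relative log-likelihood change falls below
1e-10 or the score max-norm below 1e-8, far beyond clinical reporting
precision; the iteration cap is 100. Any coefficient exceeding 15 on the
log-odds scale while the likelihood still improves raises an explicit
separation error — e¹⁵ dwarfs any plausible clinical odds ratio, and a
silent divergent estimate would be worse than a failure. Wald standard
errors come from the inverse observed information at the MLE; 95% CIs are
exp(β ± 1.96·SE) and p-values are two-sided normal, matching the
conventional presentation of clinical regression tables. Profile-likelihood
intervals are out of scope.

The Hosmer–Lemeshow statistic ranks subjects by predicted probability,
splits them into g near-equal groups (g = 10, deciles of risk, by default;
tied probabilities stay together even across a nominal boundary), and sums
(O − E)² / (E(1 − E/m)) over groups; the p-value is the upper chi-squared
tail with g − 2 degrees of freedom. When tie-merging leaves exactly two
groups the statistic is still well defined and returned, but the p-value is
NaN (zero degrees of freedom); fewer than two groups is an error.

ROC AUC is the Mann–Whitney probability that a case outscores a non-case,
ties counting one-half, computed from midranks so it equals exhaustive pair
enumeration exactly.

## Development pipeline (`ghdpretest.pipeline`)

The study cohort is unbalanced (54 GHD / 26 normal), so the model is fitted
on balanced subsets: all minority-class records plus a uniform
without-replacement draw of the majority class of equal size. The
undersample-and-fit step is repeated ten times (iteration i uses seed
`base_seed + i + 1`) and the coefficient vectors are averaged element-wise
on the log-odds scale — averaging odds ratios would not commute with the
logistic link. Calibration is checked per iteration on the balanced subset;
the pipeline reports the HL p-values but does not gate on them. The
apparent AUC scores the original unbalanced cohort with the averaged model.

Note that 1:1 balancing deliberately recalibrates the intercept to a ~50%
prevalence; the slopes are the transferable quantities. The published model
should therefore be applied with caution to populations whose GHD
prevalence is far from 50%, and this package makes no attempt to
recalibrate it.

Internal validation is ten-fold cross-validation of the *entire* procedure:
within each training split the full undersample-average routine is re-run
(with a fold-specific seed stream, `base_seed + 100000·(fold+1)`, so fold
draws never collide with the full-data draws) and the held-out fold is
scored with that fold's averaged model. Folds are stratified by outcome —
with 26 minority records and 10 folds an unstratified split can produce a
single-class validation fold, on which an AUC is undefined — and the
summary is the unweighted mean of per-fold AUCs. Whether the original
analysis stratified its folds is unknown; stratification is this package's
choice.

## Published risk model (`ghdpretest.risk`)

The shipped model is `P = e^z/(1+e^z)` with `z = 1.82·D − 1.27·S − 1.77`
(D = other deficits, S = IGF-I SDS), carried as a frozen constant with
provenance `"published"`, distinct from anything the pipeline fits. The
IGF-I SDS cut-off for any target probability q is the closed-form inversion
`S* = (logit(q) − β₀ − β_D·D)/β_S`; at q ∈ {0.25, 0.5, 0.75} this
reproduces the published six-entry cut-off table to within ±0.015 — exact
agreement to a third decimal is unattainable because the published
coefficients are themselves rounded to two decimals. Cut-offs are reported
rounded half-away-from-zero to two decimals, full precision retained
internally. Risk classes are strict: P < 25% low, P > 75% high, boundary
values intermediate; boundary comparisons use a 1e-12 absolute tolerance so
a probability recovered by floating-point inversion of a cut-off still
lands in the boundary class.

## Bayesian interpreter (`ghdpretest.bayes`)

Posterior probability follows Bayes' theorem with the test's sensitivity
and specificity; a *positive* result is a deficient GH response (the test
is a test for GHD — the sign convention is stated to avoid confusion). The
default characteristics are sensitivity = specificity = 0.90, the working
assumption for both stimulation tests; the literature ranges are exposed as
named constants. Two algebraic identities anchor the flow-chart logic at
these defaults: a prior of exactly 25% maps to exactly 75% after a positive
result, and 75% maps to 25% after a negative one — hence a low-risk
patient's single deficient response can never confirm GHD (posterior stays
below 75%) and a high-risk patient's single normal response can never
exclude it. The flow-chart turns this into recommendations: confident prior
contradicted by the result → advise a second stimulation test; confident
prior confirmed → conclude. For intermediate priors (25–75%) the original
flow-chart's branching is not fully specified; this implementation follows
the test result and always reports the posterior, which is the main
decision this package had to take on its own.

## Synthetic cohort (`ghdpretest.cohort`)

Raw patient data are not publicly deposited, so a generator emulates the
study population's structure: GHD prevalence 54/80; within-group Gaussian
IGF-I SDS (GHD −1.03 ± 0.90, normal −0.16 ± 0.89); within-group deficit
prevalence (72.2% vs 30.8%); group Gaussians for age (49.9 ± 11.8 vs
43.3 ± 14.8 y, clipped to [18, 90]) and BMI (26.7 ± 5.2 vs 25.1 ± 5.8
kg/m², clipped to [15, 60]); female fraction 37% vs 50%. The published
text and its summary table disagree on the class split (24/56 vs 26/54);
the defaults follow the table, whose percentages are internally consistent
with 26/54. Age and BMI are generated but unused by the model — the groups
did not differ in BMI — and exist to exercise the I/O schema.

Covariates are conditionally independent given the label, because only
marginal group statistics are published; any real covariance (e.g. between
IGF-I SDS and the number of deficient axes) is not represented, and
passing recovery tests therefore demonstrate correctness of the procedure
under this idealised structure, not performance on real patients. Under
equal (pooled) group variances the generative posterior log-odds are
exactly linear, giving closed-form true coefficients: slope
(μ_GHD − μ_normal)/σ̄² ≈ −1.082 per SDS unit and deficit coefficient
logit(0.722) − logit(0.308) ≈ 1.764. The pooled variance weights the two
group variances by prevalence — with printed SDs of 0.90 and 0.89 the
equal-variance identity is an excellent approximation, and any reasonable
pooling rule agrees to the third decimal. These closed forms are the
parameter-recovery oracle: the averaged-model slopes on a 20,000-record
default cohort must land within ±0.1 of them.

Optional simulation of both stimulation tests draws each test's result
deficient with probability `sens` for GHD patients and `1 − spec`
otherwise, independently per test, then fabricates a peak-GH value on the
correct side of the patient's BMI-class threshold so the concordant /
discordant exclusion flow can be reconstructed by re-classification.

## Problem sizes and numerical choices

Moment-fidelity checks run at n = 100,000 (standard errors ≲ 0.005);
parameter recovery at n = 20,000; the null cross-validation property at
n = 2,000; the apparent-AUC plausibility band over 200 seeded replicates at
the study size n = 80, inside which the published apparent AUC of 0.826
must fall within the central 95% band — a coverage check, not an equality.
At n = 80 a balanced 26/26 subset can occasionally separate; such seeds
raise the documented error and are excluded from the band (about 1% of
seeds). All randomness flows through `numpy.random.default_rng` seeds;
identical seeds give byte-identical JSON outputs.

## Known limitations

* The generator cannot reproduce the original Table-2 odds ratios or the
  0.826 / 0.820 AUCs as point values — those depend on the unavailable raw
  cohort; only distributional plausibility is checked.
* A perfectly class-ordering predictor cannot be cross-validated: every
  training fit would correctly raise the separation error, so the
  idealised "every fold AUC = 1" case is replaced by a
  strong-but-overlapping predictor in the tests.
* The model carries no age or BMI terms and assumes the ~50% effective
  prevalence induced by balanced fitting; no recalibration to other
  prevalences is provided.
* The HL group count, CI method and fold stratification of the original
  analysis are not documented; conventional defaults (g = 10, Wald 1.96,
  stratified folds) are used.
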