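# Methods

## Generative model

Each of the 18 neuroanatomical structures is modeled as linear in
intracranial volume with a common line for both sexes:

    E[Vol | ICV, sex] = intercept + slope · ICV + sex_offset · 1[male]

ICV is normal per sex (defaults: men 1666.8 ± 122.9 ml, women
1453.6 ± 113.5 ml, 450/516 subjects); height is normal per sex with a
within-sex correlation to ICV of 0.5 (configurable; the published
cohort does not report this value, but a clearly nonzero one is needed
for the multicollinearity behavior of height-adjusted ANCOVA to
manifest); age and diastolic blood pressure are independent normals.
Structures are conditionally independent given ICV — an untested
simplification; real structures share segmentation noise and biology
beyond head size, so cross-structure covariances (and any statistic
built on them) are outside what this generator can validate.

**Calibration.**  `hunt_default_spec()` solves each structure's
(slope, intercept) from the two per-sex points (mean ICV, mean volume)
of the published uncorrected group statistics, and sets the noise SD so
the marginal per-sex variance matches the average of the two published
group variances: `noise_sd² = mean(sd_m², sd_f²) − slope² · icv_sd²`
with `icv_sd² = mean(122.9², 113.5²)`.  Two-point calibration absorbs
any true sex effect into the common line, so the default spec is a
*scaling-only null*: group means are reproduced in expectation, yet no
structure differs between the sexes at equal ICV.  Sex effects for
power studies are injected explicitly via `sex_offset`.

Under this calibration the intercepts split exactly as the bias
analysis expects: all gray-matter structures positive (group A, from
+0.18 ml for the amygdala to +131 ml for cerebral cortex), cerebral
white matter and all ventricles negative (group B, −0.3 to −60 ml),
CSF near zero (+0.05 ml, near-proportional).  Cerebellar white matter
calibrates slightly positive (+5.2 ml) — consistent with the published
proportions-method direction for that structure (larger in women, an
A-type response), though anatomically it is white matter.

**Noise family.**  Volumes are drawn from a gamma distribution with
mean on the regression line and the calibrated SD (shape `(mean/sd)²`,
scale `sd²/mean`).  For every structure whose mean is many SDs above
zero this is indistinguishable from a normal; for the ventricles, whose
line means approach their SDs at small head sizes (lateral ventricle:
mean ≈ 12 ml, SD ≈ 11.5 ml at ICV 1200), it is right-skewed — as real
ventricular volumes are.  The alternative of redrawing or truncating
negative normal draws was measured to bias the female lateral-ventricle
mean upward by ≈ 1.6 ml, which breaks both moment fidelity and OLS
parameter recovery; the gamma family keeps the first two moments exact
on strictly positive support.  A structure whose line mean is
nonpositive for more than 1% of subjects is rejected with an error; the
astronomically rare subject beyond that (|z| > 4.5 in ICV) has their
line mean floored at 5% of the noise SD.

## Correction methods and inference

* **Proportions**: `Vol / ICV × ICV_ref`, `ICV_ref` defaulting to the
  analyzed table's mean ICV.  Group tests are plain pooled-variance
  Student t (Welch by flag) — deliberately naive, since the point of
  the audit is what this method reports.
* **Residuals**: `Vol_adj = Vol − b (ICV − ICV̄)` with `b` and `ICV̄`
  from OLS over the entire table (both groups pooled — appropriate when
  comparing two healthy groups; fits from a declared reference sample
  can be passed in for patient designs).  Corrected volumes are exactly
  mean-preserving and exactly decorrelated from ICV over the fitting
  sample.  A group × ICV interaction p-value (slope-homogeneity check)
  is computed and logged as a warning below 0.05, not used to abort.
* **ANCOVA**: `Vol ~ group + covariates` via statsmodels, covariates
  from {ICV, age, height, DBP}; rank-deficient designs raise an error
  naming the collinear columns, missing values raise rather than being
  listwise-deleted.

**Group inference on residuals-corrected data.**  The group contrast is
tested as the coefficient of the group indicator in
`corrected ~ group + ICV` — numerically identical (to machine
precision) to the ICV-only ANCOVA t, which is the precise sense in
which the residuals and ANCOVA methods are the same method.  A plain
two-sample t on the corrected values is *not* equivalent when the
groups differ in mean ICV: the marginal slope then partially absorbs
the group contrast and the naive t is biased toward zero (measured
type-I rate ≈ 0.01 at α = 0.05 with the default sex-ICV gap, versus
the exact 0.05 for the adjusted contrast).  `compare_groups` selects
the adjusted contrast automatically for residuals-corrected tables and
the plain t otherwise; both flavors are available explicitly.

**Multiple testing.**  Holm's step-down procedure over the 18
structures of one method (one family per method), implemented directly
and cross-checked against statsmodels in the test suite.  Direction
labels are assigned only to Holm-significant structures.

**Effect sizes.**  `cohens_d` offers the df-weighted pooled SD
(default) and the unweighted `sqrt((sd1² + sd2²)/2)` variant; the
published worked-example values are reproduced at two decimals by the
unweighted variant (the two coincide for equal group sizes).

## Subsample designs

**ICV matching.**  Cross-sex pairs within a 10-ml caliper, solved
exactly by a non-crossing dynamic program over the two ICV-sorted
lists: maximum cardinality first, minimum total |ΔICV| among maximum
matchings second, ICV ties broken by subject id.  For caliper matching
on a line an optimal non-crossing matching always exists (uncrossing
two pairs never violates the caliper and never increases cost), so the
DP is exact; the test suite verifies cardinality against a
Hopcroft–Karp oracle and cost against exhaustive enumeration.

**PPS dichotomization.**  Within one sex, assignment to the large-ICV
group is Bernoulli with probability `expit(k · z)` in the ICV z-score.
The logistic scale `k` (initial 3.0) is retuned multiplicatively
between attempts until the realized separation lies in
`target ± 0.2` with both groups holding 45–55% of subjects.  Realized
separation is normalized by the **pooled within-group SD**: the
published splits sit almost exactly two such SDs apart
(180.4 / 83.4 ≈ 2.16 for men), whereas in whole-sample SD units no
near-balanced monotone assignment can exceed `2·sqrt(2/π) ≈ 1.60`, so
"two SDs apart" is only meaningful on the within-group scale.  With
the default target the simulated male groups land within ~25 ml of the
published 1758.6 / 1578.2 ml.

## Stratification

Half-open 100-ml bins `[1000, 2100)`, lower edge inclusive; bins with
fewer than 5 subjects are reported but excluded from analysis.  Tissue
classes are exact sums (cortical GM = cerebral + cerebellar cortex;
WM = cerebral + cerebellar white matter; subcortical GM = accumbens,
amygdala, caudate, hippocampus, pallidum, putamen, thalamus;
ventricles = lateral, inferior lateral, 3rd, 4th, CSF; total brain
volume belongs to no class), expressed as percent of ICV.  One-way
ANOVAs test each tissue fraction across retained bins; the two-way
sex × bin model uses Type-III sums of squares with sum-to-zero coding
and is restricted to bins containing at least two subjects of each sex
— the extreme bins are single-sex (only men reach the largest head
sizes) and would otherwise make the interaction design singular.
Partial η² is `SS_effect / (SS_effect + SS_error)`.

For noise-free `Vol = a + b·ICV` the fraction `b + a/ICV` is monotone
with sign `−sign(a)`; the trend machinery is tested against this closed
form.  With the calibrated noise, bin-mean fractions are monotone in
the well-populated strata but can wiggle in bins of n ≲ 30 (the
white-matter trend is only ~0.2 percentage points per 100 ml against a
within-bin SD of ~2), so direction checks use the n-weighted
across-bin slope and the subject-level Spearman correlation rather
than strict bin-to-bin monotonicity.

## Bias analysis

A structure is classified **A** (intercept > 2 SE above 0), **B**
(< −2 SE) or **near-proportional** (within the band; CSF in practice —
no prediction is made for it).  Predictions: A ⇒ the smaller-ICV group
appears larger under proportions correction; B ⇒ the larger-ICV group.
Prediction accuracy is the fraction correct among structures with a
Holm-significant observed direction *and* a prediction.  The closed
form behind the rule — the noise-free proportions-corrected group
difference equals `a · ICV_ref · (E[1/ICV]₁ − E[1/ICV]₂)` — is verified
exactly in the tests.  The rule describes ICV-driven bias, not a
theorem about data: an injected true sex effect opposing and dominating
the artifact defeats it (demonstrated in the tests with a +0.5 ml male
offset on a 2-ml-intercept structure, small enough that the fitted
pooled intercept stays positive).

`hypothetical_demo` reproduces the two-imaginary-structures
demonstration: two groups differing only in ICV, one A- and one B-type
structure on common lines; the proportions method reports a significant
difference in both, the residuals method in neither.

## Numerical and degenerate-input policy

* Zero-variance samples and perfect fits (noise-free synthetic data)
  resolve deterministically: contrast ≈ 0 (below 1e-8 of scale) gives
  t = 0, p = 1; a genuinely nonzero contrast with zero residual
  variance gives t = ±inf, p = 0.
* OLS through statsmodels where formula-level covariates are involved;
  the adjusted group contrast in `compare_groups` uses independent
  hand-rolled linear algebra so the equivalence with `ancova_adjust`
  is a real two-implementation check (tolerance 1e-8 relative).
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical spec + seed reproduces
  byte-identical pipeline outputs.  Cohort CSVs are written with 17
  significant digits and read with round-trip float parsing.

## Problem sizes

Simulated cohorts default to the published 966 subjects.  The
calibration checks in the test suite use 100 replicate cohorts for
parameter-recovery coverage and 500 null cohorts (9000
structure-tests) for the type-I-error band; the direction-prediction
accuracy in the acceptance script pools five replicate cohorts
(~70 significant structure-tests).

## What passing tests do and do not show

The generator realizes the scaling assumptions the corrections argue
about — linearity in ICV, nonzero intercepts, no interaction with sex —
with known truth, so the audit's conclusions about *method behavior*
(bias direction of proportions, exactness of the adjusted contrast,
ground-truth agreement ordering) are fully testable.  It does not
emulate segmentation error structure, cross-structure correlation,
age-related atrophy trajectories, or non-Gaussian ICV distributions;
agreement counts and correlation magnitudes observed on synthetic
cohorts (e.g. 18/18 at ρ ≈ 0.87) are therefore cleaner than what real
data yield, and real-data values of those statistics are not
reproduction targets.
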