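# icvnorm

Audit of head-size normalization methods for neuroanatomical volumes.

## The problem

Volumetric brain studies routinely "correct" regional volumes for
intracranial volume (ICV) before comparing groups — most often men and
women, whose mean ICVs differ by roughly two standard deviations.  Three
corrections dominate the literature and they do not agree:

* **proportions** — `Vol / ICV × ICV̄`, the classical brain-fraction;
* **residuals** — `Vol_adj = Vol − b (ICV − ICV̄)`, with `b` the OLS slope
  of volume on ICV over the whole sample and `ICV̄` the sample mean ICV;
* **ANCOVA** — test the group coefficient in `Vol ~ group + ICV (+ age,
  height, DBP, …)`.

The proportions method silently assumes `Vol ∝ ICV`, i.e. a regression
line through the origin.  In practice no structure satisfies this: for
`Vol = a + b·ICV` the expected fraction is `Vol/ICV = b + a/ICV`, so a
structure with a positive intercept (group **A**: the gray-matter
structures) shrinks *as a fraction of ICV* with growing head size, and a
structure with a negative intercept (group **B**: cerebral white matter
and the ventricles) grows.  Dividing by ICV therefore manufactures
"sex differences" whose direction is fixed by the sign of `a`: group-A
structures come out larger in whichever group has the smaller heads,
group-B structures larger in the bigger-headed group.

`icvnorm` packages this audit end to end, for methodologists and
neuroimaging statisticians who want to see — on data with a known ground
truth — which correction detects biology and which detects head size:

1. a synthetic cohort generator whose 18 structure models (slope,
   intercept, noise SD) are calibrated to the published HUNT-MRI cohort
   statistics (450 men / 516 women; ICV 1666.8 ± 122.9 vs
   1453.6 ± 113.5 ml), with *no sex effect beyond ICV* by default;
2. the three corrections behind one interface;
3. an ICV-matched cross-sex subsample (pairs ≤ 10 ml apart; exact
   maximum-cardinality, minimum-total-difference matching) as the ground
   truth, and probability-proportional-to-size dichotomization of each
   sex into small/large-ICV groups about two SDs apart;
4. 100-ml ICV stratification of the four tissue classes (cortical GM,
   WM, subcortical GM, ventricles) as percentages of ICV, with one- and
   two-way ANOVAs;
5. per-structure group comparisons with Holm familywise correction and
   Cohen's d, cross-method agreement against the matched ground truth;
6. the intercept-sign bias rule: classify each structure A/B from its
   fitted y-intercept, predict the direction of every proportions-method
   "difference", and score the prediction.

## Worked example

```
$ icvnorm run --seed 1 --out results/
{
 "seed": 1,
 "version": "0.1.0",
 "bias_accuracy": 1.0,
 "agreement_with_matched": {
  "proportions": {
   "n_structures": 18,
   "n_same_conclusion": 4,
   "fraction": 0.2222222222222222,
   "spearman_rho": 0.3787409700722394,
   "spearman_p": 0.12116422586370856
  },
  "residuals": {
   "n_structures": 18,
   "n_same_conclusion": 18,
   "fraction": 1.0,
   "spearman_rho": 0.8740970072239421,
   "spearman_p": 2.1231300937836743e-06
  }
 },
 "matched_pairs": 171
}
```

Read this as follows.  The simulated cohort contains **no sex effect
beyond ICV**, so the ICV-matched subsample (171 cross-sex pairs within
10 ml) correctly finds nothing.  The residuals method agrees with that
ground truth on 18/18 structures and correlates strongly with it
(ρ = 0.87); the proportions method agrees on only 4/18 and shows no
significant correlation.  Every Holm-significant difference the
proportions method does report has the direction predicted by the sign
of the structure's regression intercept (`bias_accuracy: 1.0`).

The per-structure detail is in `results/comparison_proportions.csv`;
an excerpt (group1 = men, group2 = women, volumes in ml):

```
                       group1_mean  group2_mean  p_holm  cohens_d direction
cerebral_cortex            418.172      438.016   0.000    -0.624  F_larger
cerebral_white_matter      444.050      435.037   0.001     0.255  M_larger
third_ventricle              1.661        1.348   0.000     0.703  M_larger
csf                          1.193        1.205   1.000    -0.040      none
```

Cortex (intercept +131 ml, group A) is declared larger in women;
cerebral white matter (−60 ml, group B) and the 3rd ventricle (−2.3 ml,
group B) larger in men; CSF, the only near-proportional structure, is
correctly null.  None of these differences exist: the same cohort under
the residuals method yields an empty significant set.

The same artifact appears with sex removed entirely: `icvnorm
dichotomize` splits a single-sex sample into small/large-ICV groups and
the proportions method reproduces the identical A/B pattern there.

## Layout

| module | contents |
| --- | --- |
| `icvnorm.hunt` | published HUNT-MRI summary statistics (inputs) |
| `icvnorm.cohort` | `StructureModel`, `CohortSpec`, calibration, generator, CSV/YAML IO |
| `icvnorm.correction` | proportions, residuals (with `RegressionFit`), ANCOVA |
| `icvnorm.sampling` | ICV-matched pairs, PPS dichotomization |
| `icvnorm.stratification` | tissue aggregates, 100-ml strata, trend ANOVAs |
| `icvnorm.comparison` | t-tests, Holm, Cohen's d, method agreement |
| `icvnorm.bias` | A/B classification, bias prediction, hypothetical demo |
| `icvnorm.pipeline` / `icvnorm.cli` | orchestration and the `icvnorm` command |

See `docs/methods.md` for the statistical model, parameter choices and
known limitations.
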