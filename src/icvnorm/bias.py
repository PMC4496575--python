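"""Intercept-sign analysis of the proportions method's systematic bias.

For a structure on the line ``Vol = a + b*ICV`` with ``a != 0``, the
proportions-corrected volume ``Vol/ICV * ICV_ref = b*ICV_ref +
a*ICV_ref/ICV + noise`` still depends on head size through ``a/ICV``.
Comparing a small-ICV group against a large-ICV group therefore yields a
spurious difference whose direction is fixed by the intercept sign:

* group A (``a > 0``, the gray-matter structures): the smaller-ICV group
  appears *larger* after proportions correction;
* group B (``a < 0``, ventricles and cerebral white matter): the
  larger-ICV group appears larger;
* near-proportional structures (``|a|`` within a small band of zero):
  no prediction.

This module classifies structures, predicts the proportions-method
direction, scores the prediction against an observed comparison report,
and reproduces the two-structure "no true difference" demonstration in
which the proportions method flags a difference the residuals method
correctly rejects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortSpec, StructureModel, generate_cohort
from .comparison import ComparisonReport, compare_groups
from .correction import RegressionFit, proportions_correct, residuals_correct

__all__ = [
    "classify_intercept",
    "predict_proportions_bias",
    "BiasReport",
    "bias_report",
    "direction_prediction_accuracy",
    "hypothetical_demo",
    "proportions_bias_sign",
]

GROUP_A = "A"
GROUP_B = "B"
NEAR_PROPORTIONAL = "near_proportional"


def classify_intercept(fit: RegressionFit, near_zero_band: float = 2.0) -> str:
    """A/B/near-proportional label from the regression y-intercept.

    ``near_zero_band`` is a multiplier of the intercept's standard error:
    intercepts within ``band * se`` of zero are called near-proportional
    (the regression line cannot be distinguished from one through the
    origin, so the bias direction is unpredictable).
    """
    band = near_zero_band * fit.se_intercept
    if fit.intercept > band:
        return GROUP_A
    if fit.intercept < -band:
        return GROUP_B
    return NEAR_PROPORTIONAL


def predict_proportions_bias(
    label: str, smaller_icv_group: str, larger_icv_group: str
) -> str | None:
    """Predicted direction of the proportions-method group difference.

    Group A structures appear larger in the smaller-ICV group, group B
    structures larger in the larger-ICV group; a near-proportional
    structure yields no prediction (``None``).
    """
    if label == GROUP_A:
        return f"{smaller_icv_group}_larger"
    if label == GROUP_B:
        return f"{larger_icv_group}_larger"
    if label == NEAR_PROPORTIONAL:
        return None
    raise ValueError(f"unknown intercept class {label!r}")


def proportions_bias_sign(
    intercept: float, icv_mean_1: float, icv_mean_2: float
) -> int:
    """Closed-form sign of the proportions-corrected difference (group1 - group2).

    For noise-free ``Vol = a + b*ICV`` the corrected group difference is
    ``a * ICV_ref * (E[1/ICV]_1 - E[1/ICV]_2)``, so its sign is
    ``sign(a) * sign(icv_mean_2 - icv_mean_1)`` — positive intercepts
    inflate whichever group has the smaller head size.
    """
    return int(np.sign(intercept) * np.sign(icv_mean_2 - icv_mean_1))


@dataclass
class BiasReport:
    """Prediction-versus-observation audit of the proportions method.

    ``table`` has one row per structure: intercept, se_intercept,
    group_label, predicted_direction, observed_direction, significant,
    correct (NaN where no prediction or no significant observation).
    ``accuracy`` is the fraction correct among structures with a
    Holm-significant observed direction *and* a prediction.
    """

    table: pd.DataFrame
    groups: tuple[str, str]
    smaller_icv_group: str
    accuracy: float


def bias_report(
    fits: dict[str, RegressionFit],
    proportions_comparison: ComparisonReport,
    cohort: pd.DataFrame,
    grouping: str = "sex",
    near_zero_band: float = 2.0,
) -> BiasReport:
    """Score intercept-sign predictions against the observed comparison.

    Parameters
    ----------
    fits : dict
        Volume-on-ICV fits (whole sample) per structure.
    proportions_comparison : ComparisonReport
        Two-group comparison of the proportions-corrected volumes.
    cohort : DataFrame
        Used only to establish which group has the smaller mean ICV.
    """
    g1, g2 = proportions_comparison.groups
    icv1 = cohort.loc[cohort[grouping] == g1, "icv"].mean()
    icv2 = cohort.loc[cohort[grouping] == g2, "icv"].mean()
    smaller, larger = (g1, g2) if icv1 < icv2 else (g2, g1)
    rows = []
    for s in proportions_comparison.table.index:
        fit = fits[s]
        label = classify_intercept(fit, near_zero_band)
        predicted = predict_proportions_bias(label, smaller, larger)
        obs_row = proportions_comparison.table.loc[s]
        observed = obs_row["direction"] if obs_row["significant"] else None
        correct = (
            (predicted == observed)
            if (predicted is not None and observed is not None)
            else None
        )
        rows.append(
            {
                "structure": s,
                "intercept": fit.intercept,
                "se_intercept": fit.se_intercept,
                "group_label": label,
                "predicted_direction": predicted,
                "observed_direction": observed,
                "significant": bool(obs_row["significant"]),
                "correct": correct,
            }
        )
    table = pd.DataFrame(rows).set_index("structure")
    scored = table["correct"].dropna()
    accuracy = float(scored.mean()) if len(scored) else float("nan")
    return BiasReport(
        table=table,
        groups=(g1, g2),
        smaller_icv_group=smaller,
        accuracy=accuracy,
    )


def direction_prediction_accuracy(report: BiasReport) -> float:
    """Fraction of significant, predicted structures whose observed
    proportions-method direction matches the intercept-sign prediction.

    Raises
    ------
    ValueError
        If no structure has both a significant observed direction and a
        prediction (empty denominator).
    """
    scored = report.table["correct"].dropna()
    if scored.empty:
        raise ValueError(
            "no structure has a significant observed direction and a prediction"
        )
    return float(scored.mean())


def hypothetical_demo(
    seed: int = 0,
    n_per_group: int = 450,
    icv_small: tuple[float, float] = (1453.6, 113.5),
    icv_large: tuple[float, float] = (1666.8, 122.9),
    intercepts: tuple[float, float] = (3.1, -24.5),
) -> pd.DataFrame:
    """Two imaginary structures with no true group difference.

    Generates two groups that differ only in their ICV distribution and
    two structures lying on common nonzero-intercept lines (one positive,
    group A; one negative, group B).  A sex difference is clearly absent
    by construction, yet the proportions method reports one in both
    structures while the residuals method does not.

    Returns
    -------
    pandas.DataFrame
        One row per structure: intercept class, proportions-method p and
        direction, residuals-method p and direction.
    """
    # hippocampus-like (A) and lateral-ventricle-like (B) lines by default
    models = (
        StructureModel("structure_a", slope=0.0027, intercept=intercepts[0], noise_sd=0.6),
        StructureModel("structure_b", slope=0.0302, intercept=intercepts[1], noise_sd=11.0),
    )
    spec = CohortSpec(
        n_male=n_per_group,
        n_female=n_per_group,
        icv={"M": icv_large, "F": icv_small},
        age={"M": (58.7, 4.1), "F": (58.2, 4.3)},
        height={"M": (178.1, 6.0), "F": (165.1, 5.6)},
        dbp={"M": (80.0, 10.0), "F": (73.2, 10.4)},
        structures=models,
        seed=seed,
    )
    cohort = generate_cohort(spec)
    names = tuple(m.name for m in models)
    prop = compare_groups(
        proportions_correct(cohort), grouping="sex", structures=names
    )
    resid = compare_groups(
        residuals_correct(cohort), grouping="sex", structures=names
    )
    rows = []
    for m in models:
        rows.append(
            {
                "structure": m.name,
                "intercept": m.intercept,
                "group_label": (
                    GROUP_A if m.intercept > 0
                    else GROUP_B if m.intercept < 0
                    else NEAR_PROPORTIONAL
                ),
                "proportions_p": float(prop.table.loc[m.name, "p_holm"]),
                "proportions_direction": prop.table.loc[m.name, "direction"],
                "residuals_p": float(resid.table.loc[m.name, "p_holm"]),
                "residuals_direction": resid.table.loc[m.name, "direction"],
            }
        )
    return pd.DataFrame(rows).set_index("structure")
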