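"""Published summary statistics of the HUNT-MRI cohort.

The HUNT-MRI study (a substudy of the Nord-Trøndelag Health Study, Norway)
imaged 1006 adults aged 50-65; after quality control 966 subjects (450 men,
516 women) remained.  The individual-level data are not publicly deposited,
but the published group-level statistics below — per-sex moments of ICV and
covariates, and per-structure group means/SDs of the 18 FreeSurfer-derived
neuroanatomical volumes under each head-size correction — are sufficient to
calibrate a generative model (:func:`icvnorm.cohort.hunt_default_spec`) and
to serve as worked-example inputs for effect-size computations.

All volumes are in ml, heights in cm, DBP in mmHg, ages in years.
"""

from __future__ import annotations

import pandas as pd

#: Canonical snake_case names of the 18 neuroanatomical structures, in the
#: order they are conventionally tabulated.  Bilateral structures are the
#: sum of the two hemispheres.
STRUCTURES: tuple[str, ...] = (
    "accumbens",
    "amygdala",
    "brainstem",
    "caudate",
    "cerebellar_cortex",
    "cerebellar_white_matter",
    "cerebral_cortex",
    "cerebral_white_matter",
    "csf",
    "hippocampus",
    "inferior_lateral_ventricle",
    "lateral_ventricle",
    "pallidum",
    "putamen",
    "thalamus",
    "total_brain_volume",
    "third_ventricle",
    "fourth_ventricle",
)

#: Constituents of the four brain tissue classes.  ``total_brain_volume`` is
#: a summary measure and belongs to no class.
TISSUE_CLASSES: dict[str, tuple[str, ...]] = {
    "cortical_gm": ("cerebral_cortex", "cerebellar_cortex"),
    "white_matter": ("cerebral_white_matter", "cerebellar_white_matter"),
    "subcortical_gm": (
        "accumbens",
        "amygdala",
        "caudate",
        "hippocampus",
        "pallidum",
        "putamen",
        "thalamus",
    ),
    "ventricles": (
        "third_ventricle",
        "fourth_ventricle",
        "inferior_lateral_ventricle",
        "lateral_ventricle",
        "csf",
    ),
}

#: Per-sex sample sizes and covariate moments of the analyzed sample.
PARTICIPANTS = {
    "n_male": 450,
    "n_female": 516,
    "icv": {"M": (1666.8, 122.9), "F": (1453.6, 113.5)},
    "age": {"M": (58.7, 4.1), "F": (58.2, 4.3)},
    "height": {"M": (178.1, 6.0), "F": (165.1, 5.6)},
    "dbp": {"M": (80.0, 10.0), "F": (73.2, 10.4)},
}

#: ICV-matched cross-sex subsample: 152 pairs differing by <= 10 ml.
MATCHED_SUBSAMPLE = {
    "n_pairs": 152,
    "icv": {"M": (1554.1, 87.2), "F": (1554.5, 87.0)},
    "age": {"M": (58.5, 4.4), "F": (57.8, 4.2)},
}

#: Realized ICV of the sex-specific large/small dichotomized groups.
PPS_SUBSAMPLES = {
    "M": {"large": (1758.6, 77.7), "small": (1578.2, 88.7)},
    "F": {"large": (1529.4, 77.1), "small": (1380.2, 93.0)},
}

# Per-structure group mean (SD) under each treatment of head size:
# uncorrected full sample (450 M / 516 F), ICV-matched subsample (152/152),
# proportions-corrected and residuals-corrected full sample.
_COLUMNS = (
    "uncorrected_m", "uncorrected_f",
    "matched_m", "matched_f",
    "proportions_m", "proportions_f",
    "residuals_m", "residuals_f",
)

_VOLUME_ROWS = {
    # structure: ((mean, sd) x 8 columns)
    "accumbens": ((1.16, 0.18), (1.06, 0.17), (1.11, 0.18), (1.12, 0.18),
                  (1.09, 0.16), (1.13, 0.17), (1.11, 0.17), (1.11, 0.16)),
    "amygdala": ((2.99, 0.37), (2.63, 0.34), (2.89, 0.35), (2.75, 0.36),
                 (2.79, 0.33), (2.82, 0.33), (2.83, 0.34), (2.77, 0.31)),
    "brainstem": ((22.21, 2.28), (19.56, 1.97), (20.87, 2.04), (20.51, 1.87),
                  (20.71, 1.70), (20.94, 1.80), (20.91, 1.81), (20.70, 1.62)),
    "caudate": ((7.39, 0.93), (6.71, 0.90), (7.02, 0.89), (7.03, 1.02),
                (6.89, 0.78), (7.18, 0.85), (7.01, 0.82), (7.04, 0.80)),
    "cerebellar_cortex": ((107.58, 9.54), (96.16, 9.19), (103.60, 8.77),
                          (99.98, 9.12), (100.48, 8.57), (102.98, 9.05),
                          (102.45, 8.55), (100.63, 7.97)),
    "cerebellar_white_matter": ((27.82, 3.53), (24.93, 3.19), (26.04, 2.99),
                                (26.51, 2.80), (25.93, 2.72), (26.66, 2.92),
                                (26.16, 2.96), (26.38, 2.70)),
    "cerebral_cortex": ((450.94, 37.61), (410.06, 37.43), (425.27, 32.82),
                        (433.32, 38.73), (420.55, 24.25), (438.47, 27.18),
                        (426.44, 25.49), (431.43, 25.44)),
    "cerebral_white_matter": ((474.27, 54.59), (405.95, 48.38),
                              (433.37, 46.00), (440.76, 42.40),
                              (441.29, 31.32), (433.11, 31.94),
                              (435.97, 32.33), (439.35, 29.17)),
    "csf": ((1.30, 0.29), (1.14, 0.31), (1.23, 0.27), (1.23, 0.37),
            (1.22, 0.26), (1.21, 0.29), (1.21, 0.28), (1.22, 0.28)),
    "hippocampus": ((7.67, 0.73), (7.09, 0.68), (7.35, 0.70), (7.37, 0.69),
                    (7.17, 0.66), (7.60, 0.71), (7.37, 0.65), (7.35, 0.61)),
    "inferior_lateral_ventricle": ((1.12, 0.55), (0.81, 0.39), (1.06, 0.54),
                                   (0.93, 0.41), (1.04, 0.50), (0.86, 0.41),
                                   (1.00, 0.54), (0.91, 0.38)),
    "lateral_ventricle": ((25.85, 12.86), (19.41, 11.19), (23.18, 11.92),
                          (22.98, 13.69), (23.96, 11.47), (20.55, 11.18),
                          (22.30, 12.29), (22.51, 10.53)),
    "pallidum": ((3.47, 0.42), (3.19, 0.40), (3.29, 0.40), (3.30, 0.40),
                 (3.24, 0.36), (3.42, 0.43), (3.32, 0.38), (3.32, 0.38)),
    "putamen": ((10.88, 1.15), (9.94, 1.03), (10.44, 1.09), (10.37, 1.08),
                (10.16, 1.07), (10.65, 1.06), (10.43, 1.08), (10.33, 0.94)),
    "thalamus": ((13.00, 1.24), (11.67, 1.18), (12.32, 1.26), (12.23, 1.25),
                 (12.13, 0.91), (12.49, 1.07), (12.30, 0.96), (12.28, 0.98)),
    "total_brain_volume": ((1115.09, 94.55), (986.41, 89.44),
                           (1040.20, 79.70), (1052.06, 83.88),
                           (1039.09, 45.98), (1054.02, 51.57),
                           (1042.88, 49.14), (1049.38, 48.85)),
    "third_ventricle": ((1.80, 0.56), (1.28, 0.45), (1.65, 0.52),
                        (1.43, 0.54), (1.67, 0.49), (1.36, 0.45),
                        (1.58, 0.53), (1.47, 0.43)),
    "fourth_ventricle": ((2.18, 0.65), (1.86, 0.54), (2.05, 0.58),
                         (1.97, 0.61), (2.04, 0.59), (1.99, 0.57),
                         (2.05, 0.64), (1.98, 0.53)),
}


def volume_reference() -> pd.DataFrame:
    """Published per-structure group statistics as a tidy DataFrame.

    Returns
    -------
    pandas.DataFrame
        Indexed by structure name with columns ``<column>_mean`` and
        ``<column>_sd`` for each of: uncorrected_m/f, matched_m/f,
        proportions_m/f, residuals_m/f.
    """
    records = {}
    for structure, cells in _VOLUME_ROWS.items():
        row = {}
        for col, (mean, sd) in zip(_COLUMNS, cells):
            row[f"{col}_mean"] = mean
            row[f"{col}_sd"] = sd
        records[structure] = row
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "structure"
    return out.loc[list(STRUCTURES)]
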