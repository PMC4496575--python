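"""Head-size correction methods: proportions, residuals, ANCOVA.

Three ways of removing intracranial-volume (ICV) variation from a
structure volume ``Vol``:

* **proportions** — ``Vol / ICV * ICV_ref``, the classical "brain
  fraction" rescaled to the sample-mean head size.  Unbiased only if the
  structure is directly proportional to ICV (regression through the
  origin), which holds for none of the structures studied here.
* **residuals** — ``Vol_adj = Vol - b (ICV - ICVbar)`` where ``b`` is the
  OLS slope of Vol on ICV over the whole sample and ``ICVbar`` the sample
  mean ICV.  Corrected volumes are decorrelated from ICV and keep the raw
  sample mean.
* **ANCOVA** — test the group effect in ``Vol ~ group + ICV (+ extra
  covariates)``.  With ICV as the only covariate the group t is the exact
  covariate-adjusted contrast to which the residuals method aspires.

The regression sample for the residuals method defaults to the entire
table (both groups pooled), which is the recommended practice when
comparing two healthy groups; pass precomputed ``fits`` to correct against
a declared reference sample (e.g. controls only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "RegressionFit",
    "CorrectedTable",
    "AncovaResult",
    "MulticollinearityError",
    "proportions_correct",
    "fit_icv_regression",
    "fit_all_structures",
    "residuals_correct",
    "ancova_adjust",
]

_COVARIATE_CHOICES = ("icv", "age", "height", "dbp")

#: Non-volume columns of a cohort table; everything else is a structure.
BASE_COLUMNS = ("subject_id", "sex", "age", "icv", "height", "dbp", "icv_group")


class MulticollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of one structure's volume on ICV.

    Houses the symbols of the residuals correction: slope ``b``,
    y-intercept, and the mean ICV of the fitting sample.  When the fit was
    computed with a grouping, ``slope_interaction_p`` holds the p-value of
    the group x ICV interaction (slope-homogeneity check).
    """

    structure: str
    slope: float
    intercept: float
    se_intercept: float
    icv_mean: float
    n: int
    r2: float
    slope_interaction_p: float | None = None

    @property
    def b(self) -> float:
        return self.slope

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression fit needs n >= 3")
        if self.icv_mean <= 0:
            raise ValueError("icv_mean must be positive")
        if not 0 <= self.r2 <= 1:
            raise ValueError("r2 must lie in [0, 1]")


@dataclass
class CorrectedTable:
    """A cohort table whose structure columns hold corrected volumes."""

    data: pd.DataFrame
    method: str  # "proportions" | "residuals"
    fits: dict[str, RegressionFit] | None = None
    reference_icv: float | None = None


@dataclass(frozen=True)
class AncovaResult:
    """Group contrast from ``Vol ~ group + covariates``."""

    structure: str
    group_levels: tuple[str, str]
    group_coef: float  # mean(level 1) - mean(level 2), covariate-adjusted
    group_se: float
    group_t: float
    group_p: float
    df_resid: float
    covariate_coefs: dict = field(default_factory=dict)
    n: int = 0


def structure_columns(table: pd.DataFrame) -> list[str]:
    """Structure (volume) columns of a cohort-shaped table, in table order."""
    return [c for c in table.columns if c not in BASE_COLUMNS]


_structure_columns = structure_columns


def proportions_correct(
    cohort: pd.DataFrame, reference_icv: float | None = None
) -> CorrectedTable:
    """Proportions ("brain fraction") correction.

    Each volume is divided by the subject's ICV and multiplied by the
    reference ICV — by default the mean ICV of the input table, so the
    corrected values stay on the ml scale of the raw data.

    Raises
    ------
    ValueError
        If any subject has nonpositive ICV.
    """
    if (cohort["icv"] <= 0).any():
        bad = cohort.loc[cohort["icv"] <= 0, "subject_id"].tolist()
        raise ValueError(f"nonpositive ICV for subjects {bad}")
    ref = float(cohort["icv"].mean()) if reference_icv is None else float(reference_icv)
    out = cohort.copy()
    scale = ref / cohort["icv"].to_numpy()
    for col in _structure_columns(cohort):
        out[col] = cohort[col].to_numpy() * scale
    return CorrectedTable(data=out, method="proportions", reference_icv=ref)


def fit_icv_regression(
    cohort: pd.DataFrame, structure: str, grouping: str | None = None
) -> RegressionFit:
    """OLS of one structure's volume on ICV over the whole input table.

    With ``grouping`` (a column name, e.g. ``"sex"``), additionally fits
    ``Vol ~ ICV * group`` and stores the interaction p-value: similar
    slopes across groups are a precondition for pooling the regression.

    Raises
    ------
    ValueError
        Fewer than 3 subjects, or zero ICV variance (undefined slope).
    """
    if structure not in cohort.columns:
        raise KeyError(f"no column {structure!r} in cohort table")
    n = len(cohort)
    if n < 3:
        raise ValueError("need at least 3 subjects to fit a regression")
    icv = cohort["icv"].to_numpy(float)
    if np.ptp(icv) == 0:
        raise ValueError("ICV has zero variance; slope undefined")
    model = smf.ols(f"{structure} ~ icv", data=cohort).fit()
    interaction_p = None
    if grouping is not None:
        inter = smf.ols(f"{structure} ~ icv * C({grouping})", data=cohort).fit()
        # p-value of the (first) group x ICV interaction term
        term = [t for t in inter.params.index if t.startswith("icv:")]
        interaction_p = float(inter.pvalues[term[0]])
    return RegressionFit(
        structure=structure,
        slope=float(model.params["icv"]),
        intercept=float(model.params["Intercept"]),
        se_intercept=float(model.bse["Intercept"]),
        icv_mean=float(icv.mean()),
        n=n,
        r2=float(min(max(model.rsquared, 0.0), 1.0))
        if np.isfinite(model.rsquared) else 0.0,
        slope_interaction_p=interaction_p,
    )


def fit_all_structures(
    cohort: pd.DataFrame, grouping: str | None = None
) -> dict[str, RegressionFit]:
    """Volume-on-ICV fits for every structure column present."""
    return {
        s: fit_icv_regression(cohort, s, grouping=grouping)
        for s in _structure_columns(cohort)
    }


def residuals_correct(
    cohort: pd.DataFrame, fits: dict[str, RegressionFit] | None = None
) -> CorrectedTable:
    """Residuals correction: ``Vol_adj = Vol - b (ICV - ICVbar)``.

    ``fits`` defaults to OLS fits computed on this table; supply fits from
    a reference sample (e.g. controls) for two-group patient designs.

    Over the fitting sample the corrected volumes are mean-preserving and
    uncorrelated with ICV (OLS orthogonality).
    """
    if fits is None:
        fits = fit_all_structures(cohort)
    out = cohort.copy()
    icv = cohort["icv"].to_numpy(float)
    for col in _structure_columns(cohort):
        if col not in fits:
            raise KeyError(f"no regression fit supplied for structure {col!r}")
        f = fits[col]
        out[col] = cohort[col].to_numpy(float) - f.slope * (icv - f.icv_mean)
    return CorrectedTable(data=out, method="residuals", fits=dict(fits))


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name columns whose removal restores full column rank
    offending = [
        design.columns[j]
        for j in range(X.shape[1])
        if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
    ]
    raise MulticollinearityError(
        f"design matrix is rank deficient; collinear columns: {offending}"
    )


def ancova_adjust(
    cohort: pd.DataFrame,
    structure: str,
    covariates: tuple[str, ...] = ("icv",),
    group: str = "sex",
) -> AncovaResult:
    """Group contrast from the linear model ``Vol ~ group + covariates``.

    Parameters
    ----------
    cohort : DataFrame
        Raw (uncorrected) cohort table.
    structure : str
        Structure column to model.
    covariates : tuple of str
        Subset of ``("icv", "age", "height", "dbp")``.
    group : str
        Two-level grouping column.  The reported coefficient is the
        adjusted mean difference level1 - level2, levels in reverse-sorted
        order so that for sex the contrast is men minus women.

    Raises
    ------
    MulticollinearityError
        Rank-deficient design (names the offending columns).
    ValueError
        Unknown or missing-valued covariates.
    """
    unknown = [c for c in covariates if c not in _COVARIATE_CHOICES]
    if unknown:
        raise ValueError(f"unsupported covariates {unknown}; choose from {_COVARIATE_CHOICES}")
    cols = [structure, group, *covariates]
    missing_cols = [c for c in cols if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks columns {missing_cols}")
    sub = cohort[cols]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}; refusing silent deletion")
    levels = sorted(sub[group].unique(), reverse=True)
    if len(levels) != 2:
        raise ValueError(f"grouping column {group!r} must have exactly 2 levels")
    design = pd.DataFrame(
        {"const": 1.0, "group": (sub[group] == levels[0]).astype(float)}
    )
    for c in covariates:
        design[c] = sub[c].astype(float)
    _check_full_rank(design)
    formula = f"{structure} ~ C({group}, Treatment(reference={levels[1]!r}))" + "".join(
        f" + {c}" for c in covariates
    )
    fit = smf.ols(formula, data=sub).fit()
    group_term = next(t for t in fit.params.index if t.startswith(f"C({group}"))
    coef = float(fit.params[group_term])
    se = float(fit.bse[group_term])
    t_stat = float(fit.tvalues[group_term])
    p = float(fit.pvalues[group_term])
    # A numerically perfect fit (noise-free synthetic data) leaves se ~ 0 and
    # the t undefined; resolve by the size of the contrast itself.
    scale = max(1.0, float(np.abs(sub[structure]).mean()))
    if se <= 1e-10 * scale or not np.isfinite(t_stat):
        if abs(coef) <= 1e-8 * scale:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.copysign(math.inf, coef), 0.0
    return AncovaResult(
        structure=structure,
        group_levels=(str(levels[0]), str(levels[1])),
        group_coef=coef,
        group_se=se,
        group_t=t_stat,
        group_p=p,
        df_resid=float(fit.df_resid),
        covariate_coefs={c: float(fit.params[c]) for c in covariates},
        n=len(sub),
    )
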