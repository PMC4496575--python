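"""ICV stratification of brain tissue proportions.

For a structure following ``Vol = a + b * ICV``, the expected fraction of
ICV is ``Vol/ICV = b + a/ICV``: decreasing in ICV when the intercept is
positive and increasing when it is negative.  Stratifying subjects into
100-ml ICV bins and tabulating each tissue class as a percentage of ICV
makes this allometric non-proportionality directly visible — gray matter
fractions fall with head size while white matter and ventricular
fractions rise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .hunt import TISSUE_CLASSES

__all__ = [
    "tissue_aggregates",
    "StrataTable",
    "stratify_icv",
    "TrendTest",
    "proportion_trend_tests",
    "expected_fraction_slope_sign",
]

TISSUES = tuple(TISSUE_CLASSES)


def tissue_aggregates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject tissue-class volumes (ml), as exact constituent sums.

    Classes: cortical_gm = cerebral + cerebellar cortex; white_matter =
    cerebral + cerebellar white matter; subcortical_gm = the seven deep
    gray structures; ventricles = lateral, inferior lateral, 3rd, 4th
    ventricles + CSF.  ``total_brain_volume`` belongs to no class.

    Raises
    ------
    KeyError
        A constituent structure column is missing.
    """
    out = {}
    for tissue, parts in TISSUE_CLASSES.items():
        missing = [p for p in parts if p not in cohort.columns]
        if missing:
            raise KeyError(f"{tissue}: missing structure columns {missing}")
        out[tissue] = cohort[list(parts)].sum(axis=1)
    return pd.DataFrame(out, index=cohort.index)


@dataclass
class StrataTable:
    """Tissue percentages of ICV by 100-ml ICV stratum.

    ``table`` has one row per bin with columns bin_lower, bin_upper, n,
    retained, and ``<tissue>_pct_mean`` / ``<tissue>_pct_sd`` for the four
    tissue classes.  Bins under ``min_n`` subjects are reported but
    flagged ``retained=False``; ``n_outside`` counts subjects whose ICV
    falls outside the binned range entirely.
    """

    table: pd.DataFrame
    bin_width: float
    start: float
    min_n: int
    n_outside: int

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]


def _bin_lower(icv: np.ndarray, start: float, width: float) -> np.ndarray:
    return start + np.floor((icv - start) / width) * width


def stratify_icv(
    cohort: pd.DataFrame,
    bin_width: float = 100.0,
    start: float = 1000.0,
    n_bins: int = 11,
    min_n: int = 5,
) -> StrataTable:
    """Stratify subjects into half-open ICV bins and summarize fractions.

    Bins are ``[start + k*width, start + (k+1)*width)`` for k = 0..n_bins-1
    (default 1000-2100 ml); a subject with ICV exactly on an edge belongs
    to the upper bin.  Bins with fewer than ``min_n`` subjects are flagged
    and excluded from trend analysis.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    icv = cohort["icv"].to_numpy(float)
    aggs = tissue_aggregates(cohort)
    pct = aggs.div(cohort["icv"], axis=0) * 100.0
    lower = _bin_lower(icv, start, bin_width)
    inside = (icv >= start) & (icv < start + n_bins * bin_width)
    rows = []
    for k in range(n_bins):
        lo = start + k * bin_width
        mask = inside & (lower == lo)
        n = int(mask.sum())
        row = {
            "bin_lower": lo,
            "bin_upper": lo + bin_width,
            "n": n,
            "retained": n >= min_n,
        }
        for tissue in TISSUES:
            vals = pct.loc[mask, tissue]
            row[f"{tissue}_pct_mean"] = float(vals.mean()) if n else np.nan
            row[f"{tissue}_pct_sd"] = float(vals.std(ddof=1)) if n > 1 else np.nan
        rows.append(row)
    return StrataTable(
        table=pd.DataFrame(rows),
        bin_width=float(bin_width),
        start=float(start),
        min_n=int(min_n),
        n_outside=int((~inside).sum()),
    )


@dataclass(frozen=True)
class TrendTest:
    """ANOVA of one tissue fraction across ICV strata."""

    tissue: str
    f: float
    p: float
    partial_eta_sq: float
    df_effect: float
    df_error: float


def _partial_eta(ss_effect: float, ss_error: float) -> float:
    return ss_effect / (ss_effect + ss_error) if (ss_effect + ss_error) > 0 else 0.0


def proportion_trend_tests(
    cohort: pd.DataFrame, strata: StrataTable | None = None
) -> dict:
    """One-way (ICV bin) and two-way (sex x bin) ANOVAs on tissue fractions.

    Subjects in retained bins only.  The one-way analysis tests whether
    each tissue's percentage of ICV varies across strata; the two-way
    analysis (Type-III sums of squares, sum-to-zero coding) adds sex and
    the sex x bin interaction.  Partial eta-squared is
    ``SS_effect / (SS_effect + SS_error)``.

    Returns
    -------
    dict
        ``{"one_way": {tissue: TrendTest}, "two_way": {tissue: {effect:
        TrendTest}}}`` with effects ``sex``, ``icv_bin``, ``sex_x_bin``.
    """
    if strata is None:
        strata = stratify_icv(cohort)
    kept = strata.retained
    if len(kept) < 2:
        raise ValueError("need at least 2 retained ICV strata for trend tests")
    icv = cohort["icv"].to_numpy(float)
    lower = _bin_lower(icv, strata.start, strata.bin_width)
    keep_mask = np.isin(lower, kept["bin_lower"].to_numpy())
    sub = cohort[keep_mask].copy()
    pct = tissue_aggregates(sub).div(sub["icv"], axis=0) * 100.0
    frame = pd.DataFrame(
        {
            "icv_bin": pd.Categorical(_bin_lower(sub["icv"].to_numpy(float),
                                                 strata.start, strata.bin_width)),
            "sex": sub["sex"].to_numpy(),
        }
    )
    # the sex x bin model needs both sexes in every cell: edge strata are
    # often single-sex (only men reach the largest head sizes) and would
    # make the interaction design singular
    cell_counts = frame.groupby(["icv_bin", "sex"], observed=True).size().unstack(
        fill_value=0
    )
    both_sexes = cell_counts.index[(cell_counts >= 2).all(axis=1)]
    two_way_mask = frame["icv_bin"].isin(both_sexes).to_numpy()
    one_way: dict[str, TrendTest] = {}
    two_way: dict[str, dict[str, TrendTest]] = {}
    for tissue in TISSUES:
        frame["y"] = pct[tissue].to_numpy()
        if frame.groupby("icv_bin", observed=True)["y"].var().fillna(0).eq(0).all():
            raise ValueError(f"{tissue}: degenerate (zero-variance) strata")
        fit1 = smf.ols("y ~ C(icv_bin)", data=frame).fit()
        a1 = sm.stats.anova_lm(fit1, typ=1)
        ss_b, ss_w = a1["sum_sq"].iloc[0], a1["sum_sq"].iloc[1]
        one_way[tissue] = TrendTest(
            tissue=tissue,
            f=float(a1["F"].iloc[0]),
            p=float(a1["PR(>F)"].iloc[0]),
            partial_eta_sq=_partial_eta(ss_b, ss_w),
            df_effect=float(a1["df"].iloc[0]),
            df_error=float(a1["df"].iloc[1]),
        )
        if frame["sex"].nunique() == 2 and len(both_sexes) >= 2:
            frame2 = frame[two_way_mask].copy()
            frame2["icv_bin"] = frame2["icv_bin"].cat.remove_unused_categories()
            fit2 = smf.ols(
                "y ~ C(sex, Sum) * C(icv_bin, Sum)", data=frame2
            ).fit()
            a2 = sm.stats.anova_lm(fit2, typ=3)
            ss_err = float(a2.loc["Residual", "sum_sq"])
            effects = {
                "sex": "C(sex, Sum)",
                "icv_bin": "C(icv_bin, Sum)",
                "sex_x_bin": "C(sex, Sum):C(icv_bin, Sum)",
            }
            two_way[tissue] = {}
            for label, term in effects.items():
                ss = float(a2.loc[term, "sum_sq"])
                two_way[tissue][label] = TrendTest(
                    tissue=tissue,
                    f=float(a2.loc[term, "F"]),
                    p=float(a2.loc[term, "PR(>F)"]),
                    partial_eta_sq=_partial_eta(ss, ss_err),
                    df_effect=float(a2.loc[term, "df"]),
                    df_error=float(a2.loc["Residual", "df"]),
                )
    return {"one_way": one_way, "two_way": two_way}


def expected_fraction_slope_sign(intercept: float) -> int:
    """Sign of d(E[Vol/ICV])/d(ICV) for Vol = a + b*ICV: -sign(a)."""
    return -int(np.sign(intercept))
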