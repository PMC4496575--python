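"""End-to-end audit pipeline.

Orchestrates: cohort simulation (or CSV load) -> head-size corrections ->
ICV-matched ground-truth subsample -> sex-specific PPS dichotomization ->
ICV stratification of tissue fractions -> per-structure Holm-corrected
group comparisons -> intercept-sign bias audit -> cross-method agreement.
Every stage writes CSV/JSON reports into the output directory; the same
config and seed reproduce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bias import bias_report
from .cohort import generate_cohort, hunt_default_spec, read_cohort
from .comparison import compare_groups, interaction_screen, method_agreement
from .correction import ancova_adjust, fit_all_structures, proportions_correct, residuals_correct, structure_columns
from .sampling import match_by_icv, pps_dichotomize
from .stratification import proportion_trend_tests, stratify_icv

logger = logging.getLogger("icvnorm")

VALID_METHODS = ("proportions", "residuals", "ancova")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``input_csv=None`` simulates the default calibrated cohort instead of
    loading one.  ``ancova_covariates`` are the extra covariates beyond
    ICV used by the ancova method.
    """

    input_csv: str | None = None
    methods: tuple[str, ...] = VALID_METHODS
    matching_tolerance: float = 10.0
    pps_target_separation: float = 2.0
    bin_width: float = 100.0
    bin_start: float = 1000.0
    min_bin_n: int = 5
    alpha: float = 0.05
    ancova_covariates: tuple[str, ...] = ("icv", "age", "height", "dbp")
    seed: int = 0
    output_dir: str = "icvnorm_run"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.methods:
            raise ValueError("at least one correction method must be selected")
        bad = [m for m in self.methods if m not in VALID_METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; valid: {VALID_METHODS}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = (json.loads(text) if str(path).endswith(".json")
               else yaml.safe_load(text))
        raw["methods"] = tuple(raw.get("methods", VALID_METHODS))
        raw["ancova_covariates"] = tuple(
            raw.get("ancova_covariates", ("icv", "age", "height", "dbp"))
        )
        return cls(**raw)


def _report_frame(report) -> pd.DataFrame:
    out = report.table.copy()
    out.insert(0, "group1", report.groups[0])
    out.insert(1, "group2", report.groups[1])
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full audit; returns the report bundle as a dict.

    Writes per-stage CSV/JSON files plus ``summary.json`` (seed, version,
    agreement metrics, bias accuracy) into ``config.output_dir``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)
    bundle: dict = {}

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # annotate with stage name, re-raise
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- cohort -----------------------------------------------------------
    if config.input_csv is None:
        cohort = stage("simulate", generate_cohort, hunt_default_spec(), config.seed)
    else:
        cohort = stage("load", read_cohort, config.input_csv)
    cohort.to_csv(out_dir / "cohort.csv", index=False)
    bundle["cohort"] = cohort

    # --- corrections ------------------------------------------------------
    fits = stage("fit", fit_all_structures, cohort, "sex")
    corrected = {}
    if "proportions" in config.methods:
        corrected["proportions"] = stage("correct", proportions_correct, cohort)
    if "residuals" in config.methods or "ancova" in config.methods:
        corrected["residuals"] = stage("correct", residuals_correct, cohort, fits)
    for fit in fits.values():
        if fit.slope_interaction_p is not None and fit.slope_interaction_p < 0.05:
            logger.warning(
                "slope heterogeneity: %s sex x ICV interaction p=%.3g",
                fit.structure, fit.slope_interaction_p,
            )
    bundle["fits"] = fits
    bundle["corrected"] = corrected

    # --- screens and comparisons -----------------------------------------
    bundle["interaction_screen"] = stage("screen", interaction_screen, cohort)
    bundle["interaction_screen"].to_csv(out_dir / "interaction_screen.csv")
    comparisons = {
        "uncorrected": stage("compare", compare_groups, cohort, "sex",
                             alpha=config.alpha)
    }
    for name, table in corrected.items():
        comparisons[name] = stage("compare", compare_groups, table, "sex",
                                  alpha=config.alpha)
    if "ancova" in config.methods:
        anc = {
            s: stage("compare", ancova_adjust, cohort, s,
                     tuple(config.ancova_covariates), "sex")
            for s in structure_columns(cohort)
        }
        anc_frame = pd.DataFrame(
            [dataclasses.asdict(a) for a in anc.values()]
        ).set_index("structure")
        from .comparison import holm_adjust

        anc_frame["p_holm"] = holm_adjust(anc_frame["group_p"].to_numpy())
        anc_frame.to_csv(out_dir / "comparison_ancova.csv")
        bundle["ancova"] = anc_frame
    for name, rep in comparisons.items():
        _report_frame(rep).to_csv(out_dir / f"comparison_{name}.csv")
    bundle["comparisons"] = comparisons

    # --- ICV-matched ground truth ----------------------------------------
    pairs = stage("match", match_by_icv, cohort, config.matching_tolerance)
    matched = pairs.subsample(cohort)
    pd.DataFrame(pairs.pairs, columns=["male_id", "female_id", "icv_difference"]).to_csv(
        out_dir / "matched_pairs.csv", index=False
    )
    matched_report = stage("compare", compare_groups, matched, "sex",
                           alpha=config.alpha)
    _report_frame(matched_report).to_csv(out_dir / "comparison_matched.csv")
    bundle["matched_pairs"] = pairs
    bundle["comparisons"]["matched"] = matched_report

    # --- sex-specific dichotomization ------------------------------------
    pps = {}
    for sex in ("M", "F"):
        sub = cohort[cohort["sex"] == sex].reset_index(drop=True)
        split = stage("dichotomize", pps_dichotomize, sub,
                      config.pps_target_separation, config.seed)
        with_group = split.with_group_column(sub)
        reports = {}
        if "proportions" in corrected:
            reports["proportions"] = compare_groups(
                proportions_correct(with_group), "icv_group",
                levels=("large", "small"), alpha=config.alpha,
            )
        if "residuals" in corrected:
            reports["residuals"] = compare_groups(
                residuals_correct(with_group), "icv_group",
                levels=("large", "small"), alpha=config.alpha,
            )
        for mname, rep in reports.items():
            _report_frame(rep).to_csv(out_dir / f"comparison_{sex}_{mname}.csv")
        pps[sex] = {"split": split, "reports": reports}
    bundle["pps"] = pps

    # --- stratification ---------------------------------------------------
    strata = stage("stratify", stratify_icv, cohort, config.bin_width,
                   config.bin_start, 11, config.min_bin_n)
    strata.table.to_csv(out_dir / "strata.csv", index=False)
    trends = stage("stratify", proportion_trend_tests, cohort, strata)
    trend_json = {
        "one_way": {t: dataclasses.asdict(v) for t, v in trends["one_way"].items()},
        "two_way": {
            t: {e: dataclasses.asdict(v) for e, v in d.items()}
            for t, d in trends["two_way"].items()
        },
    }
    (out_dir / "trend_tests.json").write_text(json.dumps(trend_json, indent=1))
    bundle["strata"] = strata
    bundle["trends"] = trends

    # --- bias audit and agreement ----------------------------------------
    config_echo = dataclasses.asdict(config)
    config_echo.pop("output_dir")  # numeric outputs must not depend on it
    summary = {"seed": config.seed, "version": __version__, "config": config_echo}
    if "proportions" in comparisons:
        audit = stage("bias", bias_report, fits, comparisons["proportions"], cohort)
        audit.table.to_csv(out_dir / "bias_report.csv")
        bundle["bias"] = audit
        summary["bias_accuracy"] = audit.accuracy
    agreement = {}
    for name in corrected:
        agr = method_agreement(comparisons[name], bundle["comparisons"]["matched"])
        agreement[name] = dataclasses.asdict(agr)
    summary["agreement_with_matched"] = agreement
    summary["matched_pairs"] = len(pairs)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    bundle["summary"] = summary
    return bundle
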