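"""Synthetic cohort generation.

Volumetric studies of head-size correction need subject-level data with a
known generative truth.  This module provides a per-structure linear-in-ICV
Gaussian model,

    Vol = intercept + slope * ICV + sex_offset * 1[male] + eps,
    eps ~ Normal(0, noise_sd),

with sex-specific ICV distributions.  The key feature is a *nonzero*
intercept: every structure scales linearly but not proportionally with ICV,
which is exactly the regime in which ratio-based ("proportions") correction
is biased.  With all ``sex_offset`` set to zero the generator realizes the
scaling-only null: sexes differ in ICV but share one volume-vs-ICV line, so
any "sex difference" a correction method reports is an artifact of the
method.

:func:`hunt_default_spec` calibrates the 18 structure models so that the
per-sex group means reproduce the published uncorrected HUNT-MRI values
(see :mod:`icvnorm.hunt`).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hunt import PARTICIPANTS, STRUCTURES, volume_reference

__all__ = [
    "StructureModel",
    "CohortSpec",
    "calibrate_linear_model",
    "hunt_default_spec",
    "generate_cohort",
    "validate_cohort",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]

#: Fixed CSV header of a cohort table.
COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "sex",
    "age",
    "icv",
    "height",
    "dbp",
) + STRUCTURES

@dataclass(frozen=True)
class StructureModel:
    """Linear-in-ICV generative model for one structure (all in ml).

    ``sex_offset`` is added to the male mean; with the default 0 the
    structure has no sex effect beyond ICV by construction.
    """

    name: str
    slope: float
    intercept: float
    noise_sd: float
    sex_offset: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope):
            raise ValueError(f"{self.name}: slope must be finite")
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a two-sex cohort.

    Per-sex dictionaries are keyed ``"M"``/``"F"`` with ``(mean, sd)``
    tuples; units are ml (ICV), years (age), cm (height), mmHg (DBP).
    ``height_icv_corr`` is the within-sex correlation between height and
    ICV.  Age and DBP are drawn independently of ICV.
    """

    n_male: int
    n_female: int
    icv: dict
    age: dict
    height: dict
    dbp: dict
    structures: tuple[StructureModel, ...]
    height_icv_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male <= 0 or self.n_female <= 0:
            raise ValueError("sex counts must be positive")
        if not abs(self.height_icv_corr) < 1:
            raise ValueError("|height_icv_corr| must be < 1")
        for attr in ("icv", "age", "height", "dbp"):
            dist = getattr(self, attr)
            for sex in ("M", "F"):
                mean, sd = dist[sex]
                if sd <= 0:
                    raise ValueError(f"{attr}[{sex}]: sd must be > 0")

    # -- serialization (round-trip exact) --------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["structures"] = [dataclasses.asdict(s) for s in self.structures]
        for attr in ("icv", "age", "height", "dbp"):
            d[attr] = {k: list(v) for k, v in d[attr].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["structures"] = tuple(StructureModel(**s) for s in d["structures"])
        for attr in ("icv", "age", "height", "dbp"):
            d[attr] = {k: tuple(v) for k, v in d[attr].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def calibrate_linear_model(
    name: str,
    mean_m: float,
    mean_f: float,
    icv_mean_m: float,
    icv_mean_f: float,
    sd_m: float,
    sd_f: float,
    icv_sd: float,
) -> StructureModel:
    """Two-point calibration of a structure model from group statistics.

    Solves for the unique line through the two per-sex (ICV mean, volume
    mean) points and sets the residual noise so that the model's marginal
    per-sex SD matches the average of the observed group variances:

        slope     = (mean_m - mean_f) / (icv_mean_m - icv_mean_f)
        intercept = mean_m - slope * icv_mean_m
        noise_sd  = sqrt(max(0, mean(sd_m^2, sd_f^2) - slope^2 * icv_sd^2))

    Any true sex effect is absorbed into the common line (sex_offset = 0),
    so the calibrated model is a scaling-only null that reproduces the
    observed group means exactly in expectation.

    Raises
    ------
    ValueError
        If the two group ICV means coincide (calibration impossible).
    """
    if icv_mean_m == icv_mean_f:
        raise ValueError(
            f"{name}: group ICV means are equal; two-point calibration impossible"
        )
    slope = float((mean_m - mean_f) / (icv_mean_m - icv_mean_f))
    intercept = float(mean_m - slope * icv_mean_m)
    noise_var = 0.5 * (sd_m**2 + sd_f**2) - slope**2 * icv_sd**2
    noise_sd = math.sqrt(max(0.0, float(noise_var)))
    return StructureModel(name=name, slope=slope, intercept=intercept, noise_sd=noise_sd)


def hunt_default_spec() -> CohortSpec:
    """Cohort spec calibrated to the published HUNT-MRI statistics.

    450 men / 516 women; per-sex ICV, age, height and DBP moments as
    published; all 18 structure models two-point calibrated from the
    uncorrected group means and SDs (scaling-only null: no sex offsets).
    Deterministic — involves no randomness.
    """
    ref = volume_reference()
    icv_m, icv_sd_m = PARTICIPANTS["icv"]["M"]
    icv_f, icv_sd_f = PARTICIPANTS["icv"]["F"]
    icv_sd = math.sqrt(0.5 * (icv_sd_m**2 + icv_sd_f**2))
    structures = tuple(
        calibrate_linear_model(
            name,
            mean_m=ref.loc[name, "uncorrected_m_mean"],
            mean_f=ref.loc[name, "uncorrected_f_mean"],
            icv_mean_m=icv_m,
            icv_mean_f=icv_f,
            sd_m=ref.loc[name, "uncorrected_m_sd"],
            sd_f=ref.loc[name, "uncorrected_f_sd"],
            icv_sd=icv_sd,
        )
        for name in STRUCTURES
    )
    return CohortSpec(
        n_male=PARTICIPANTS["n_male"],
        n_female=PARTICIPANTS["n_female"],
        icv=dict(PARTICIPANTS["icv"]),
        age=dict(PARTICIPANTS["age"]),
        height=dict(PARTICIPANTS["height"]),
        dbp=dict(PARTICIPANTS["dbp"]),
        structures=structures,
    )


def _draw_volume(
    rng: np.random.Generator, mean: np.ndarray, sd: float, what: str
) -> np.ndarray:
    """Positive volume draws with exact mean and SD.

    Volumes are gamma-distributed around the regression line: shape
    ``(mean/sd)^2``, scale ``sd^2/mean``, giving exactly the requested
    first two moments on strictly positive support.  For mean >> sd (all
    the gray-matter structures) this is indistinguishable from a normal;
    for the ventricles, whose means approach their SDs at small head
    sizes, it is right-skewed — as real ventricular volumes are.
    Truncating or redrawing a normal instead would silently bias the
    conditional mean off the line.
    """
    mean = np.asarray(mean, dtype=float)
    bad = mean <= 0
    if sd == 0:
        if bad.any():
            raise ValueError(
                f"{what}: regression line gives nonpositive expected volume"
            )
        return mean.copy()
    if bad.mean() > 0.01:
        raise ValueError(
            f"{what}: regression line gives nonpositive expected volume for "
            f"{bad.mean():.0%} of subjects"
        )
    # an extreme-ICV subject can push a ventricle's line mean through zero;
    # floor such rare cases at a sliver of the noise SD instead of failing
    mean = np.maximum(mean, 0.05 * sd)
    shape = (mean / sd) ** 2
    return rng.gamma(shape, (sd**2) / mean)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table from a :class:`CohortSpec`.

    ICV is normal per sex; height is drawn with the configured within-sex
    correlation to ICV; age and DBP are independent normals.  Each
    structure is drawn around its regression line with SD ``noise_sd``,
    conditionally independent of the other structures given ICV (see
    :func:`_draw_volume` for the positivity-preserving noise family).

    Parameters
    ----------
    spec : CohortSpec
    seed : int, optional
        Overrides ``spec.seed``.  Same (spec, seed) gives an identical
        table.

    Returns
    -------
    pandas.DataFrame
        Columns :data:`COHORT_COLUMNS`; one row per subject.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    rho = spec.height_icv_corr
    for sex, n in (("M", spec.n_male), ("F", spec.n_female)):
        icv_mean, icv_sd = spec.icv[sex]
        z_icv = rng.standard_normal(n)
        icv = icv_mean + icv_sd * z_icv
        if np.any(icv <= 0):
            raise ValueError("drew nonpositive ICV; check spec moments")
        h_mean, h_sd = spec.height[sex]
        height = h_mean + h_sd * (
            rho * z_icv + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        )
        age = rng.normal(*spec.age[sex], size=n)
        dbp = rng.normal(*spec.dbp[sex], size=n)
        cols = {
            "sex": np.repeat(sex, n),
            "age": age,
            "icv": icv,
            "height": height,
            "dbp": dbp,
        }
        for sm in spec.structures:
            mean = sm.intercept + sm.slope * icv
            if sex == "M":
                mean = mean + sm.sex_offset
            cols[sm.name] = _draw_volume(rng, mean, sm.noise_sd, f"{sm.name}/{sex}")
        frames.append(pd.DataFrame(cols))
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(table))])
    order = ["subject_id", "sex", "age", "icv", "height", "dbp"] + [
        sm.name for sm in spec.structures
    ]
    return table[order]


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort table against the documented schema.

    Requires every canonical column, strictly positive ICV and nonnegative
    volumes.  Returns the table with columns in canonical order.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if not set(table["sex"].unique()) <= {"M", "F"}:
        raise ValueError("sex column must contain only 'M'/'F'")
    if (table["icv"] <= 0).any():
        raise ValueError("ICV must be strictly positive")
    vols = table[list(STRUCTURES)]
    if (vols.to_numpy() < 0).any():
        raise ValueError("structure volumes must be nonnegative")
    return table[list(COHORT_COLUMNS)]


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV with the fixed documented header.

    Floats are written with 17 significant digits so a read-back is
    bit-exact.
    """
    validate_cohort(table).to_csv(path, index=False, float_format="%.17g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    Uses round-trip float parsing so a write/read cycle is bit-exact.
    """
    return validate_cohort(pd.read_csv(path, float_precision="round_trip"))
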