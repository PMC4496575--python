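"""Subsample construction: cross-sex ICV matching and PPS dichotomization.

Two complementary designs isolate head size from sex:

* :func:`match_by_icv` pairs each man with a woman whose ICV differs by at
  most a caliper (default 10 ml).  Within the matched subsample the sexes
  have near-identical ICV distributions, so any remaining volume
  difference is attributable to sex — the study's "ground truth".
* :func:`pps_dichotomize` splits a *single-sex* sample into small- and
  large-ICV groups by probability-proportional-to-size assignment, so
  that the groups differ in head size but, by construction, not in sex.
  A correction method that still reports group differences there is
  detecting ICV, not biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["MatchedPairs", "match_by_icv", "DichotomizedSample", "pps_dichotomize"]


@dataclass(frozen=True)
class MatchedPairs:
    """One-to-one cross-sex pairs within an ICV caliper.

    ``pairs`` is a list of ``(male_id, female_id, icv_difference)`` with
    ``icv_difference = male ICV - female ICV``; every absolute difference
    respects ``tolerance`` and no subject appears twice.
    """

    pairs: tuple[tuple[str, str, float], ...]
    tolerance: float

    def __len__(self) -> int:
        return len(self.pairs)

    def subsample(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Rows of ``cohort`` belonging to matched subjects."""
        ids = {m for m, _, _ in self.pairs} | {f for _, f, _ in self.pairs}
        return cohort[cohort["subject_id"].isin(ids)].reset_index(drop=True)


def match_by_icv(cohort: pd.DataFrame, tolerance: float = 10.0) -> MatchedPairs:
    """Maximum-cardinality cross-sex ICV matching within a caliper.

    Among all matchings of maximum size, returns one minimizing the total
    absolute ICV difference.  Both objectives are solved exactly by a
    non-crossing dynamic program over the two ICV-sorted lists: for
    caliper matching on a line, any crossing pair of edges can be
    uncrossed without losing feasibility or increasing cost, so an
    optimal non-crossing matching always exists.  Ties in ICV are broken
    by subject id, making the result deterministic.

    Raises
    ------
    ValueError
        Negative tolerance or a missing sex.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    men = cohort[cohort["sex"] == "M"]
    women = cohort[cohort["sex"] == "F"]
    if men.empty or women.empty:
        raise ValueError("both sexes must be present to match")
    m = men[["subject_id", "icv"]].sort_values(["icv", "subject_id"]).to_numpy()
    w = women[["subject_id", "icv"]].sort_values(["icv", "subject_id"]).to_numpy()
    m_icv = m[:, 1].astype(float)
    w_icv = w[:, 1].astype(float)
    nm, nw = len(m), len(w)

    # dp over suffixes: value = (#pairs, min total cost), lexicographic
    pairs_dp = np.zeros((nm + 1, nw + 1), dtype=np.int64)
    cost_dp = np.zeros((nm + 1, nw + 1), dtype=float)
    choice = np.zeros((nm + 1, nw + 1), dtype=np.int8)  # 0 skip-m, 1 skip-w, 2 pair
    for i in range(nm - 1, -1, -1):
        for j in range(nw - 1, -1, -1):
            best_p, best_c, best_ch = pairs_dp[i + 1, j], cost_dp[i + 1, j], 0
            p, c = pairs_dp[i, j + 1], cost_dp[i, j + 1]
            if p > best_p or (p == best_p and c < best_c):
                best_p, best_c, best_ch = p, c, 1
            d = abs(m_icv[i] - w_icv[j])
            if d <= tolerance:
                p, c = pairs_dp[i + 1, j + 1] + 1, cost_dp[i + 1, j + 1] + d
                if p > best_p or (p == best_p and c < best_c):
                    best_p, best_c, best_ch = p, c, 2
            pairs_dp[i, j] = best_p
            cost_dp[i, j] = best_c
            choice[i, j] = best_ch
    out = []
    i = j = 0
    while i < nm and j < nw:
        ch = choice[i, j]
        if ch == 2:
            out.append((str(m[i, 0]), str(w[j, 0]), float(m_icv[i] - w_icv[j])))
            i += 1
            j += 1
        elif ch == 0:
            i += 1
        else:
            j += 1
    return MatchedPairs(pairs=tuple(out), tolerance=float(tolerance))


@dataclass(frozen=True)
class DichotomizedSample:
    """Small/large-ICV split of a single-sex sample.

    ``assignment`` maps subject id to ``"small"``/``"large"``.  The
    realized ``separation`` is (mean_large - mean_small) divided by the
    pooled within-group ICV SD, the scale on which the published splits
    sit about two SDs apart.
    """

    assignment: dict
    separation: float
    seed: int
    logistic_scale: float

    def subsample(self, cohort: pd.DataFrame, group: str) -> pd.DataFrame:
        ids = {k for k, v in self.assignment.items() if v == group}
        return cohort[cohort["subject_id"].isin(ids)].reset_index(drop=True)

    def with_group_column(self, cohort: pd.DataFrame) -> pd.DataFrame:
        out = cohort.copy()
        out["icv_group"] = out["subject_id"].map(self.assignment)
        if out["icv_group"].isna().any():
            raise ValueError("cohort contains subjects outside the assignment")
        return out


def _separation(icv: np.ndarray, large: np.ndarray) -> float:
    g_l, g_s = icv[large], icv[~large]
    sp = np.sqrt(
        ((len(g_l) - 1) * g_l.var(ddof=1) + (len(g_s) - 1) * g_s.var(ddof=1))
        / (len(g_l) + len(g_s) - 2)
    )
    return float((g_l.mean() - g_s.mean()) / sp)


def pps_dichotomize(
    cohort_one_sex: pd.DataFrame,
    target_separation_sd: float = 2.0,
    seed: int = 0,
    band: float = 0.2,
    max_attempts: int = 1000,
) -> DichotomizedSample:
    """Probability-proportional-to-size split into small/large ICV groups.

    Assignment to the large group is Bernoulli with probability
    ``expit(k * z)`` where ``z`` is the ICV z-score — subjects with larger
    than average ICV are more likely to land in the large group.  The
    logistic scale ``k`` is retuned between attempts until the realized
    separation falls within ``target_separation_sd ± band`` (pooled
    within-group SD units) with both groups holding 45-55% of subjects.

    Raises
    ------
    ValueError
        Nonpositive target, n < 20, constant ICV, or the target still
        unmet after ``max_attempts`` (the error reports the best realized
        separation).
    """
    if target_separation_sd <= 0:
        raise ValueError("target separation must be positive (groups must differ)")
    if len(cohort_one_sex) < 20:
        raise ValueError("need at least 20 subjects to dichotomize")
    if cohort_one_sex["sex"].nunique() != 1:
        raise ValueError("pps_dichotomize expects a single-sex table")
    icv = cohort_one_sex["icv"].to_numpy(float)
    sd = icv.std(ddof=1)
    if sd == 0:
        raise ValueError("all ICV equal: no separation achievable")
    z = (icv - icv.mean()) / sd
    ids = cohort_one_sex["subject_id"].to_numpy()
    n = len(icv)
    k = 3.0
    best: tuple[float, np.ndarray, float] | None = None  # (|gap|, large, sep)
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        large = rng.random(n) < expit(k * z)
        n_large = int(large.sum())
        if not (0.45 * n <= n_large <= 0.55 * n) or n_large in (0, n):
            continue
        sep = _separation(icv, large)
        gap = abs(sep - target_separation_sd)
        if best is None or gap < best[0]:
            best = (gap, large, sep)
        if gap <= band:
            assignment = {
                str(i): ("large" if lg else "small") for i, lg in zip(ids, large)
            }
            return DichotomizedSample(
                assignment=assignment,
                separation=sep,
                seed=seed,
                logistic_scale=k,
            )
        # multiplicative retune toward the target, clipped to sane range
        k = float(np.clip(k * target_separation_sd / max(sep, 1e-6), 0.05, 50.0))
    achieved = best[2] if best is not None else float("nan")
    raise ValueError(
        f"target separation {target_separation_sd} unmet after {max_attempts} "
        f"attempts; best realized {achieved:.3f}"
    )
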