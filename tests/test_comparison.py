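"""Effect sizes, Holm correction, group comparison and method agreement."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from icvnorm import (
    cohens_d,
    compare_groups,
    generate_cohort,
    holm_adjust,
    interaction_screen,
    match_by_icv,
    method_agreement,
    proportions_correct,
    residuals_correct,
    volume_reference,
)

# (column pair, structure, published |d|) for the worked examples; the
# average-variance pooled SD reproduces every printed value at 2 decimals
PRINTED_D = [
    ("matched", "cerebral_cortex", 152, 152, 0.22),
    ("matched", "inferior_lateral_ventricle", 152, 152, 0.27),
    ("residuals", "cerebral_cortex", 450, 516, 0.20),
    ("residuals", "inferior_lateral_ventricle", 450, 516, 0.19),
    ("residuals", "amygdala", 450, 516, 0.18),
]


class TestCohensD:
    @pytest.mark.parametrize("col,structure,n1,n2,expected", PRINTED_D)
    def test_printed_effect_sizes(self, col, structure, n1, n2, expected):
        ref = volume_reference()
        d = cohens_d(
            ref.loc[structure, f"{col}_m_mean"],
            ref.loc[structure, f"{col}_m_sd"],
            n1,
            ref.loc[structure, f"{col}_f_mean"],
            ref.loc[structure, f"{col}_f_sd"],
            n2,
            variant="average",
        )
        assert round(abs(d), 2) == expected

    def test_equal_means_give_zero(self):
        assert cohens_d(5.0, 1.0, 10, 5.0, 2.0, 12) == 0.0

    def test_zero_pooled_sd_with_unequal_means_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            cohens_d(5.0, 0.0, 10, 4.0, 0.0, 12)

    @given(
        m1=st.floats(-50, 50), m2=st.floats(-50, 50),
        s1=st.floats(0.1, 10), s2=st.floats(0.1, 10),
        n1=st.integers(2, 500), n2=st.integers(2, 500),
        scale=st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetric_and_scale_invariant(self, m1, m2, s1, s2, n1, n2, scale):
        d = cohens_d(m1, s1, n1, m2, s2, n2)
        assert cohens_d(m2, s2, n2, m1, s1, n1) == pytest.approx(-d, rel=1e-9)
        assert cohens_d(
            m1 * scale, s1 * scale, n1, m2 * scale, s2 * scale, n2
        ) == pytest.approx(d, rel=1e-6)


class TestHolm:
    def test_hand_computed_step_down(self):
        assert np.allclose(holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.4]) == pytest.approx([0.4])

    def test_ties_capped_at_one(self):
        assert np.allclose(holm_adjust([0.5, 0.5]), [1.0, 1.0])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_statsmodels_and_dominance(self, ps):
        ours = holm_adjust(ps)
        theirs = multipletests(ps, method="holm")[1]
        assert np.allclose(ours, theirs, atol=1e-12)
        alpha = 0.05
        p = np.asarray(ps)
        holm_rej = ours < alpha
        bonf_rej = np.minimum(p * len(p), 1) < alpha
        raw_rej = p < alpha
        assert np.all(holm_rej >= bonf_rej)   # Holm rejects a superset
        assert np.all(holm_rej <= raw_rej)    # never beyond unadjusted


class TestCompareGroups:
    def test_report_invariants(self, cohort):
        rep = compare_groups(proportions_correct(cohort), "sex")
        t = rep.table
        assert (t["p_holm"] >= t["p_raw"] - 1e-15).all()
        assert (t.loc[t["significant"], "p_holm"] < 0.05).all()
        assert ((t["direction"] == "none") == ~t["significant"]).all()
        assert rep.groups == ("M", "F")

    def test_equal_valued_groups_all_null(self, cohort):
        clone = cohort.copy()
        # give both sexes the same volumes by value: copy male block onto
        # female rows (recycled), so group means are near-identical
        rng = np.random.default_rng(0)
        for s in ("hippocampus", "thalamus"):
            vals = rng.normal(10, 1, len(clone))
            clone[s] = vals
        rep = compare_groups(clone, "sex", structures=("hippocampus", "thalamus"))
        assert not rep.table["significant"].any()

    def test_small_group_rejected(self, cohort):
        sub = cohort[cohort["sex"] == "F"].head(1)
        broken = np.vstack  # noqa: F841 - keep lint quiet
        import pandas as pd

        t = pd.concat([cohort[cohort["sex"] == "M"].head(5), sub])
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups(t, "sex")

    def test_welch_flag_changes_df(self, cohort):
        pooled = compare_groups(cohort, "sex", test="student")
        welch = compare_groups(cohort, "sex", test="welch")
        assert (pooled.table["df"] == 964).all()
        assert (welch.table["df"] != 964).any()

    def test_power_with_printed_sex_offsets(self, hunt_spec):
        # inject the published residual-method male-female differences for
        # 3rd ventricle and cerebellar cortex as true male offsets: the
        # residuals comparison detects each (men larger) in a large
        # majority of runs, the offsets being small enough that
        # familywise-corrected detection is only intermittent, and no
        # offset-free structure reaches familywise significance
        injected = {"third_ventricle": 0.11, "cerebellar_cortex": 1.82}
        structs = tuple(
            dataclasses.replace(sm, sex_offset=injected.get(sm.name, 0.0))
            for sm in hunt_spec.structures
        )
        spec = dataclasses.replace(hunt_spec, structures=structs)
        detected = {name: 0 for name in injected}
        holm_any = 0
        false_holm = 0
        seeds = range(1, 11)
        for seed in seeds:
            c = generate_cohort(spec, seed)
            rep = compare_groups(residuals_correct(c), "sex").table
            for name in injected:
                detected[name] += bool(
                    rep.loc[name, "p_raw"] < 0.05 and rep.loc[name, "t"] > 0
                )
            holm_any += rep.loc[list(injected), "significant"].any()
            false_holm += int(rep.drop(list(injected))["significant"].sum())
        for name, count in detected.items():
            assert count >= 7, (name, count)
        assert holm_any >= 3
        assert false_holm <= 2


class TestMethodAgreement:
    def test_self_agreement_is_perfect(self, cohort):
        rep = compare_groups(residuals_correct(cohort), "sex")
        agr = method_agreement(rep, rep)
        assert agr.n_same_conclusion == agr.n_structures == 18
        assert agr.spearman_rho == pytest.approx(1.0)

    def test_reversed_directions_count_only_mutual_nulls(self, hunt_spec):
        # a report whose every significant direction is flipped agrees
        # with the original only on the mutually non-significant structures
        structs = tuple(
            dataclasses.replace(
                sm, sex_offset=0.11 if sm.name == "third_ventricle" else
                (1.82 if sm.name == "cerebellar_cortex" else 0.0)
            )
            for sm in hunt_spec.structures
        )
        spec = dataclasses.replace(hunt_spec, structures=structs)
        c = generate_cohort(spec, 1)
        fwd = compare_groups(residuals_correct(c), "sex")
        rev = dataclasses.replace(fwd, table=fwd.table.copy())
        flip = {"M_larger": "F_larger", "F_larger": "M_larger", "none": "none"}
        rev.table["direction"] = rev.table["direction"].map(flip)
        n_sig = int(fwd.table["significant"].sum())
        assert n_sig >= 1
        agr = method_agreement(fwd, rev)
        assert agr.n_same_conclusion == 18 - n_sig

    def test_residuals_tracks_ground_truth_better_than_proportions(self, hunt_spec):
        for seed in (1, 2, 3, 4):
            c = generate_cohort(hunt_spec, seed)
            matched = match_by_icv(c).subsample(c)
            truth = compare_groups(matched, "sex")
            resid = method_agreement(compare_groups(residuals_correct(c), "sex"), truth)
            prop = method_agreement(compare_groups(proportions_correct(c), "sex"), truth)
            assert resid.fraction > prop.fraction, seed
            assert resid.spearman_rho > prop.spearman_rho, seed

    def test_mismatched_structures_rejected(self, cohort):
        rep = compare_groups(residuals_correct(cohort), "sex")
        other = compare_groups(
            residuals_correct(cohort), "sex", structures=("thalamus", "hippocampus")
        )
        with pytest.raises(ValueError, match="different structure"):
            method_agreement(rep, other)


def test_interaction_screen_null_on_default_cohort(cohort):
    screen = interaction_screen(cohort)
    # generator has a common slope for both sexes: Holm-corrected
    # interaction p-values should stay clear of significance
    assert (screen["p_holm_sex_x_icv"] > 0.05).all()
    assert (screen["p_holm_sex_x_age"] > 0.05).all()
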