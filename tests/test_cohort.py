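"""Synthetic cohort generator: calibration, moments, determinism, IO."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from icvnorm import (
    STRUCTURES,
    CohortSpec,
    StructureModel,
    calibrate_linear_model,
    generate_cohort,
    hunt_default_spec,
    read_cohort,
    write_cohort,
)

ICV_M, ICV_F = 1666.8, 1453.6


class TestCalibration:
    def test_total_brain_volume_two_point_solve(self):
        m = calibrate_linear_model(
            "total_brain_volume", 1115.09, 986.41, ICV_M, ICV_F, 94.55, 89.44, 118.29
        )
        assert m.slope == pytest.approx(0.6036, abs=5e-4)
        assert m.intercept == pytest.approx(109.07, abs=0.5)
        assert m.intercept > 0  # group A

    def test_cerebral_white_matter_negative_intercept(self):
        m = calibrate_linear_model(
            "cerebral_white_matter", 474.27, 405.95, ICV_M, ICV_F, 54.59, 48.38, 118.29
        )
        assert m.slope == pytest.approx(0.3204, abs=5e-4)
        assert m.intercept == pytest.approx(-59.86, abs=0.5)

    def test_equal_means_give_flat_line(self):
        m = calibrate_linear_model("x", 10.0, 10.0, ICV_M, ICV_F, 1.0, 1.0, 118.0)
        assert m.slope == 0.0
        assert m.intercept == 10.0

    def test_equal_icv_means_impossible(self):
        with pytest.raises(ValueError, match="calibration impossible"):
            calibrate_linear_model("x", 5.0, 4.0, 1500.0, 1500.0, 1.0, 1.0, 118.0)

    def test_group_means_reproduced_in_expectation(self, hunt_spec):
        # the calibrated line passes through both (ICV mean, volume mean) points
        from icvnorm import volume_reference

        ref = volume_reference()
        for sm in hunt_spec.structures:
            assert sm.intercept + sm.slope * ICV_M == pytest.approx(
                ref.loc[sm.name, "uncorrected_m_mean"], abs=1e-9
            )
            assert sm.intercept + sm.slope * ICV_F == pytest.approx(
                ref.loc[sm.name, "uncorrected_f_mean"], abs=1e-9
            )


class TestHuntDefaultSpec:
    def test_sample_sizes_and_moments(self, hunt_spec):
        assert hunt_spec.n_male + hunt_spec.n_female == 966
        assert hunt_spec.n_male == 450
        assert hunt_spec.icv["M"] == (1666.8, 122.9)
        assert hunt_spec.icv["F"] == (1453.6, 113.5)
        assert len(hunt_spec.structures) == 18

    def test_intercept_sign_pattern(self, hunt_spec):
        # gray matter scales sub-proportionally (positive intercept);
        # cerebral WM and the ventricles super-proportionally (negative);
        # CSF is near-proportional; cerebellar WM calibrates slightly positive.
        by_name = {s.name: s for s in hunt_spec.structures}
        gray = (
            "accumbens", "amygdala", "caudate", "hippocampus", "pallidum",
            "putamen", "thalamus", "cerebral_cortex", "cerebellar_cortex",
        )
        for name in gray:
            assert by_name[name].intercept > 0, name
        for name in (
            "cerebral_white_matter", "lateral_ventricle", "third_ventricle",
            "fourth_ventricle", "inferior_lateral_ventricle",
        ):
            assert by_name[name].intercept < 0, name
        assert abs(by_name["csf"].intercept) < 0.1
        assert by_name["cerebellar_white_matter"].intercept > 0

    def test_deterministic(self):
        a, b = hunt_default_spec(), hunt_default_spec()
        assert a == b


class TestGenerateCohort:
    def test_same_seed_identical(self, tiny_spec):
        t1 = generate_cohort(tiny_spec, seed=7)
        t2 = generate_cohort(tiny_spec, seed=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self, tiny_spec):
        t1 = generate_cohort(tiny_spec, seed=7)
        t2 = generate_cohort(tiny_spec, seed=8)
        assert not t1["icv"].equals(t2["icv"])

    def test_zero_noise_puts_subjects_on_the_line(self, tiny_spec):
        models = tuple(
            dataclasses.replace(m, noise_sd=0.0) for m in tiny_spec.structures
            if m.intercept >= 0  # keep volumes positive at any ICV
        )
        spec = dataclasses.replace(tiny_spec, structures=models)
        t = generate_cohort(spec, seed=3)
        for m in models:
            expected = m.intercept + m.slope * t["icv"]
            assert np.allclose(t[m.name], expected, rtol=0, atol=1e-9)

    def test_moment_fidelity_within_4_se(self, hunt_spec, cohort):
        for sex, n in (("M", 450), ("F", 516)):
            sub = cohort[cohort["sex"] == sex]
            assert len(sub) == n
            for attr in ("icv", "age", "height", "dbp"):
                mean, sd = getattr(hunt_spec, attr)[sex]
                se_mean = sd / math.sqrt(n)
                se_sd = sd / math.sqrt(2 * n)
                assert abs(sub[attr].mean() - mean) < 4 * se_mean, (sex, attr)
                assert abs(sub[attr].std(ddof=1) - sd) < 4 * se_sd, (sex, attr)

    def test_structure_means_within_3_se(self, hunt_spec, cohort):
        from icvnorm import volume_reference

        ref = volume_reference()
        for sex, col in (("M", "uncorrected_m"), ("F", "uncorrected_f")):
            sub = cohort[cohort["sex"] == sex]
            for name in STRUCTURES:
                mean = ref.loc[name, f"{col}_mean"]
                sd = ref.loc[name, f"{col}_sd"]
                se = sd / math.sqrt(len(sub))
                assert abs(sub[name].mean() - mean) < 3 * se, (sex, name)

    def test_height_icv_correlation(self, cohort):
        for sex in ("M", "F"):
            sub = cohort[cohort["sex"] == sex]
            r = np.corrcoef(sub["icv"], sub["height"])[0, 1]
            assert r == pytest.approx(0.5, abs=0.12)

    def test_intercept_sign_recovered_when_identified(self, hunt_spec, fits):
        by_name = {s.name: s for s in hunt_spec.structures}
        for name, fit in fits.items():
            if abs(fit.intercept) > 2 * fit.se_intercept:
                assert math.copysign(1, fit.intercept) == math.copysign(
                    1, by_name[name].intercept
                ), name

    def test_nonpositive_expected_volume_errors(self, tiny_spec):
        bad = (StructureModel("doomed", slope=0.0, intercept=-5.0, noise_sd=0.5),)
        spec = dataclasses.replace(tiny_spec, structures=bad)
        with pytest.raises(ValueError, match="nonpositive expected volume"):
            generate_cohort(spec, seed=0)

    def test_noisy_small_structure_stays_positive_with_right_moments(self, tiny_spec):
        small = (StructureModel("tiny", slope=0.0, intercept=0.5, noise_sd=0.4),)
        spec = dataclasses.replace(
            tiny_spec, structures=small, n_male=4000, n_female=4000
        )
        t = generate_cohort(spec, seed=0)
        assert (t["tiny"] > 0).all()
        # positivity does not come at the price of biased moments
        assert t["tiny"].mean() == pytest.approx(0.5, abs=0.02)
        assert t["tiny"].std(ddof=1) == pytest.approx(0.4, abs=0.02)


class TestValidationAndIO:
    def test_csv_round_trip_exact(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(back, cohort, check_exact=True)

    def test_spec_yaml_json_round_trip(self, hunt_spec, tmp_path):
        hunt_spec.to_yaml(tmp_path / "spec.yaml")
        assert CohortSpec.from_yaml(tmp_path / "spec.yaml") == hunt_spec
        hunt_spec.to_json(tmp_path / "spec.json")
        assert CohortSpec.from_json(tmp_path / "spec.json") == hunt_spec

    def test_invalid_specs_rejected(self, tiny_spec):
        with pytest.raises(ValueError):
            dataclasses.replace(tiny_spec, n_male=0)
        with pytest.raises(ValueError):
            dataclasses.replace(tiny_spec, height_icv_corr=1.0)
        with pytest.raises(ValueError):
            dataclasses.replace(tiny_spec, icv={"M": (1600.0, -1.0), "F": (1450.0, 100.0)})
        with pytest.raises(ValueError):
            StructureModel("x", slope=float("inf"), intercept=0.0, noise_sd=1.0)

    def test_missing_column_rejected(self, cohort, tmp_path):
        broken = cohort.drop(columns=["thalamus"])
        with pytest.raises(ValueError, match="thalamus"):
            write_cohort(broken, tmp_path / "x.csv")
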