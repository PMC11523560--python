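"""Cohort sampling and musculoskeletal scaling."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from fatiguetl.anthropometry import (GENERIC_ACTUATORS, REFERENCE,
                                     ReferenceAnthropometry, SubjectStatics,
                                     cohort_from_csv, cohort_to_csv,
                                     sample_recorded_style_cohort,
                                     sample_simulated_cohort, scale_model)


class TestSimulatedCohort:
    def test_heights_within_percentile_bounds(self):
        z = stats.norm.ppf(0.95)
        lo = REFERENCE.height_mean - z * REFERENCE.height_sd
        hi = REFERENCE.height_mean + z * REFERENCE.height_sd
        cohort = sample_simulated_cohort(300, seed=0)
        assert len(cohort) == 300
        heights = np.array([s.height for s in cohort])
        assert heights.min() >= lo and heights.max() <= hi

    def test_truncation_never_violated_large_sample(self):
        z = stats.norm.ppf(0.95)
        cohort = sample_simulated_cohort(100_000, seed=7)
        for attr, mean, sd in [("height", REFERENCE.height_mean,
                                REFERENCE.height_sd),
                               ("mass", REFERENCE.mass_mean,
                                REFERENCE.mass_sd)]:
            vals = np.array([getattr(s, attr) for s in cohort])
            assert vals.min() >= mean - z * sd - 1e-12
            assert vals.max() <= mean + z * sd + 1e-12

    def test_degenerate_sd_yields_reference_means(self):
        ref = dataclasses.replace(REFERENCE, height_sd=0.0, mass_sd=0.0,
                                  derived_noise_sd=0.0)
        (s,) = sample_simulated_cohort(1, seed=3, ref=ref)
        assert s.height == pytest.approx(ref.height_mean)
        assert s.mass == pytest.approx(ref.mass_mean)
        assert s.forearm_length == pytest.approx(ref.forearm_mean)

    def test_law_of_large_numbers_mass(self):
        cohort = sample_simulated_cohort(10_000, seed=1)
        masses = np.array([s.mass for s in cohort])
        # truncation at z=1.645 shrinks the SD; 4 naive SEs is conservative
        se = REFERENCE.mass_sd / np.sqrt(len(masses))
        assert abs(masses.mean() - REFERENCE.mass_mean) < 4 * se

    def test_seed_reproducibility_bitwise(self):
        a = sample_simulated_cohort(50, seed=9)
        b = sample_simulated_cohort(50, seed=9)
        assert a == b

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            sample_simulated_cohort(0, seed=0)


class TestRecordedStyleCohort:
    def test_masses_within_three_sd(self):
        cohort = sample_recorded_style_cohort(25, seed=0)
        assert len(cohort) == 25
        masses = np.array([s.mass for s in cohort])
        assert masses.min() >= 75.1 - 3 * 12.2
        assert masses.max() <= 75.1 + 3 * 12.2

    def test_mvc_mean_matches_recorded_statistics(self):
        cohort = sample_recorded_style_cohort(10_000, seed=2)
        mvc = np.array([s.mvc_torque for s in cohort])
        se = 14.0 / np.sqrt(len(mvc))
        assert abs(mvc.mean() - 46.9) < 4 * se

    def test_degenerate_sds_collapse_to_means(self):
        ref = ReferenceAnthropometry(height_sd=0, mass_sd=0, mvc_sd=0,
                                     forearm_sd=0, elbow_width_sd=0,
                                     upper_arm_sd=0)
        cohort = sample_recorded_style_cohort(5, seed=0, ref=ref)
        for s in cohort:
            assert s.height == pytest.approx(1.70)
            assert s.mvc_torque == pytest.approx(46.9)


class TestScaleModel:
    def test_reference_subject_is_identity(self, ref_subject):
        model = scale_model(GENERIC_ACTUATORS, ref_subject)
        for scaled, generic in zip(model.actuators, GENERIC_ACTUATORS):
            assert scaled.fmax == pytest.approx(generic.fmax)
            assert scaled.moment_arm == pytest.approx(generic.moment_arm)

    def test_height_doubles_moment_arms_only(self, ref_subject):
        tall = dataclasses.replace(ref_subject,
                                   height=2 * ref_subject.height)
        model = scale_model(GENERIC_ACTUATORS, tall)
        for scaled, generic in zip(model.actuators, GENERIC_ACTUATORS):
            assert scaled.moment_arm == pytest.approx(2 * generic.moment_arm)
            assert scaled.fmax == pytest.approx(generic.fmax)

    def test_mass_scaling_arithmetic(self, ref_subject):
        heavy = dataclasses.replace(ref_subject,
                                    mass=1.21 * ref_subject.mass)
        from fatiguetl.anthropometry import ActuatorParams
        generic = list(GENERIC_ACTUATORS[:6]) + [
            ActuatorParams("BRD", "BRD", 1000.0, 0.05)]
        model = scale_model(generic, heavy)
        assert model.actuators[-1].fmax == pytest.approx(1210.0)
        assert model.actuators[-1].moment_arm == pytest.approx(0.05)

    def test_scaling_round_trips_through_inverse(self):
        subject = sample_simulated_cohort(1, seed=5)[0]
        model = scale_model(GENERIC_ACTUATORS, subject)
        # scaling the scaled set by the inverse ratios recovers the generic set
        back = dataclasses.replace(
            subject,
            height=REFERENCE.height_mean ** 2 / subject.height,
            mass=REFERENCE.mass_mean ** 2 / subject.mass)
        restored = scale_model(model.actuators, back)
        for r, g in zip(restored.actuators, GENERIC_ACTUATORS):
            assert r.fmax == pytest.approx(g.fmax, rel=1e-12)
            assert r.moment_arm == pytest.approx(g.moment_arm, rel=1e-12)

    def test_sign_preservation_and_ceiling_band(self, ref_model):
        assert all(a.moment_arm < 0 for a in ref_model.extensors)
        assert all(a.moment_arm > 0 for a in ref_model.flexors)
        # flexion-strength ceiling of the reference subject spans the
        # target grid so that 30-90 Nm runs feasible-to-infeasible
        assert 50.0 <= ref_model.strength_ceiling <= 100.0

    def test_invalid_statics_rejected(self):
        with pytest.raises(ValueError):
            SubjectStatics("x", "male", -1.7, 75.0, 47.0, 26.0, 9.5, 31.6)


def test_cohort_csv_round_trip(tmp_path):
    cohort = sample_recorded_style_cohort(8, seed=4)
    path = tmp_path / "cohort.csv"
    cohort_to_csv(cohort, path)
    header = path.read_text().splitlines()[0]
    assert header == ("subject_id,sex,height_m,mass_kg,mvc_Nm,"
                      "forearm_cm,elbow_width_cm,upper_arm_cm")
    restored = cohort_from_csv(path)
    assert [s.subject_id for s in restored] == [s.subject_id for s in cohort]
    assert restored[3].mass == pytest.approx(cohort[3].mass)
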