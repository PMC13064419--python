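"""Synthetic generator: platform profiles, CoM dynamics, EMG forward model,
cohort structure."""
import dataclasses

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

import comfeedback as cf
from comfeedback.synthetic import G, magnitude_spec, to_agonist_frame


class TestPlatformProfile:
    def test_small_perturbation_hits_printed_peaks(self, small_platform):
        # protocol small magnitude: 11.1 cm/s and 0.15 g
        assert small_platform.v.values.max() == pytest.approx(0.111, rel=0.02)
        assert small_platform.a.values.max() == pytest.approx(0.15 * G, rel=0.02)

    def test_velocity_and_displacement_are_running_integrals(self, small_platform):
        v_ref = cumulative_trapezoid(
            small_platform.a.values, dx=small_platform.a.dt, initial=0.0
        )
        np.testing.assert_allclose(small_platform.v.values, v_ref, atol=1e-12)
        assert abs(small_platform.v.values[-1]) < 1e-10  # terminal velocity zero

    def test_backward_is_pointwise_negation(self):
        fwd = cf.make_platform_profile(magnitude_spec("small", "forward"))
        bwd = cf.make_platform_profile(magnitude_spec("small", "backward"))
        for ch in ("d", "v", "a"):
            np.testing.assert_allclose(
                getattr(bwd, ch).values, -getattr(fwd, ch).values, atol=1e-15
            )

    def test_infeasible_pulse_is_rejected(self):
        # pulse width 2V/A = 1 s exceeds the 0.5 s accel-to-decel interval
        spec = cf.PerturbationSpec("forward", 0.05, 0.5, 1.0)
        with pytest.raises(ValueError, match="infeasible"):
            cf.make_platform_profile(spec)


class TestComSimulation:
    def test_zero_input_gives_zero_response(self, small_platform, body):
        quiet = cf.ComKinematics(
            small_platform.d.with_values(np.zeros(len(small_platform.d))),
            small_platform.v.with_values(np.zeros(len(small_platform.v))),
            small_platform.a.with_values(np.zeros(len(small_platform.a))),
        )
        com = cf.simulate_com_kinematics(quiet, body)
        for ch in ("d", "v", "a"):
            np.testing.assert_allclose(getattr(com, ch).values, 0.0, atol=1e-15)

    def test_overdamped_step_response_matches_closed_form(self):
        """Constant platform acceleration: d(t) follows the analytic
        overdamped second-order step response."""
        w, z, g, u = 3.0, 1.2, 1.0, 2.0
        rate, t1 = 1000.0, 4.0
        n = int(t1 * rate) + 1
        t = np.arange(n) / rate
        a = np.full(n, u)
        mk = lambda x: cf.UniformSeries(x, 0.0, rate)
        plat = cf.ComKinematics(mk(np.zeros(n)), mk(np.zeros(n)), mk(a))
        com = cf.simulate_com_kinematics(plat, cf.BodyModel(w, z, g))
        r1 = -w * (z - np.sqrt(z * z - 1.0))
        r2 = -w * (z + np.sqrt(z * z - 1.0))
        dss = -g * u / w**2
        d_exact = dss * (1.0 - (r2 * np.exp(r1 * t) - r1 * np.exp(r2 * t)) / (r2 - r1))
        np.testing.assert_allclose(com.d.values, d_exact, atol=5e-7)
        # monotone, non-oscillatory approach to steady state
        assert np.all(np.diff(np.abs(com.d.values - dss)) <= 1e-12)

    def test_response_is_linear_in_coupling_gain(self, small_platform):
        c1 = cf.simulate_com_kinematics(small_platform, cf.BodyModel(coupling_gain=1.0))
        c2 = cf.simulate_com_kinematics(small_platform, cf.BodyModel(coupling_gain=2.0))
        for ch in ("d", "v", "a"):
            np.testing.assert_allclose(
                getattr(c2, ch).values, 2.0 * getattr(c1, ch).values, atol=1e-12
            )


class TestGenerateEmg:
    def test_zero_gains_zero_noise_gives_constant_baseline(self, com_agonist):
        zero = cf.LoopParams(0.0, 0.0, 0.0, 0.119)
        zero2 = cf.LoopParams(0.0, 0.0, 0.0, 0.200)
        truth = cf.GroundTruth(zero, zero2, zero, dataclasses.replace(zero2, sign_mode="shorten", delay=0.181),
                               baseline=0.07, noise_sd=0.0)
        emg = cf.generate_emg(com_agonist, truth, "agonist", seed=0)
        np.testing.assert_allclose(emg.values, 0.07, atol=1e-15)

    def test_noiseless_output_equals_forward_reconstruction(self, com_agonist, truth_clean):
        emg = cf.generate_emg(com_agonist, truth_clean, "agonist", seed=3)
        rec = cf.reconstruct(com_agonist, truth_clean.agonist_model("small"))
        np.testing.assert_allclose(emg.values, rec.total.values, atol=1e-15)

    def test_antagonist_uses_negated_frame(self, com_agonist, truth_clean):
        emg = cf.generate_emg(com_agonist, truth_clean, "antagonist", seed=3)
        rec = cf.reconstruct(-com_agonist, truth_clean.antagonist_model("small"))
        np.testing.assert_allclose(emg.values, rec.total.values, atol=1e-15)

    def test_same_seed_is_bit_identical(self, com_agonist):
        truth = cf.default_ground_truth(noise_sd=0.05)
        a = cf.generate_emg(com_agonist, truth, "agonist", seed=42)
        b = cf.generate_emg(com_agonist, truth, "agonist", seed=42)
        np.testing.assert_array_equal(a.values, b.values)


class TestCohort:
    def test_default_participant_has_48_trials(self):
        trials, _ = cf.generate_cohort(1, 0, seed=5)
        assert len(trials) == 48  # 8 trials x 3 magnitudes x 2 directions
        conds = {(t.direction, t.magnitude) for t in trials}
        assert len(conds) == 6

    def test_study_sized_cohort_has_36_participants(self):
        trials, reg = cf.generate_cohort(19, 17, trials_per_condition=1, seed=5)
        assert len(reg) == 36
        groups = [e["group"] for e in reg.values()]
        assert groups.count("OA") == 19 and groups.count("PD") == 17

    def test_zero_stepped_fraction_flags_nothing(self):
        trials, _ = cf.generate_cohort(1, 0, trials_per_condition=1, seed=5, stepped_fraction=0.0)
        assert not any(t.stepped for t in trials)

    def test_cohort_is_deterministic_in_seed(self):
        a, _ = cf.generate_cohort(1, 0, trials_per_condition=1, seed=9)
        b, _ = cf.generate_cohort(1, 0, trials_per_condition=1, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.emg_agonist.values, tb.emg_agonist.values)
            np.testing.assert_array_equal(ta.com.d.values, tb.com.d.values)

    def test_write_load_roundtrip(self, tmp_path):
        trials, reg = cf.generate_cohort(1, 0, trials_per_condition=1, seed=2)
        cf.write_cohort(tmp_path / "c", trials, reg)
        loaded, reg2 = cf.load_cohort(tmp_path / "c")
        assert len(loaded) == len(trials)
        np.testing.assert_allclose(
            loaded[0].emg_agonist.values, trials[0].emg_agonist.values, atol=1e-9
        )
        t0 = list(reg2.values())[0]["ground_truth"]
        assert t0.agonist_llr1 == list(reg.values())[0]["ground_truth"].agonist_llr1

    def test_separate_100hz_kinematics_mode(self, tmp_path):
        trials, reg = cf.generate_cohort(1, 0, trials_per_condition=1, seed=2)
        cf.write_cohort(tmp_path / "c100", trials, reg, com_rate=100.0)
        loaded, _ = cf.load_cohort(tmp_path / "c100")
        assert loaded[0].com.rate == pytest.approx(100.0)
        assert loaded[0].emg_agonist.rate == pytest.approx(1000.0)

    def test_direction_symmetry_of_platform_kinematics(self):
        trials, _ = cf.generate_cohort(
            1, 0, trials_per_condition=1, seed=4, kinematic_jitter=0.0
        )
        by = {(t.direction, t.magnitude): t for t in trials}
        for mag in ("small", "medium", "large"):
            f, b = by[("forward", mag)], by[("backward", mag)]
            np.testing.assert_allclose(f.com.d.values, -b.com.d.values, atol=1e-12)
            # analysis frame is identical for the two directions
            np.testing.assert_allclose(
                to_agonist_frame(f.com, "forward").d.values,
                to_agonist_frame(b.com, "backward").d.values,
                atol=1e-12,
            )
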