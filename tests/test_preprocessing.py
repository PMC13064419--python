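"""EMG envelope chain, epoching, normalization, averaging/exclusion, CoM
kinematics helpers."""
import numpy as np
import pytest
from scipy import signal as sps
from scipy.signal import savgol_filter

import comfeedback as cf
from comfeedback.preprocessing import (
    EPOCH_WINDOW,
    ExcludedCondition,
    average_condition,
    com_acceleration,
    com_velocity,
    epoch,
    normalize_participant,
    peak_excursion,
    process_emg_trial,
)
from comfeedback.series import ComKinematics, UniformSeries


def series(values, t0=-0.5, rate=1000.0):
    return UniformSeries(np.asarray(values, dtype=float), t0, rate)


def reference_chain(x, rate=1000.0, order=6):
    """Independently coded envelope chain: manual forward-backward filtering
    with even-reflection padding, same stage order."""

    def zero_phase(b, a, y):
        # forward-backward pass over an even-reflection extension, with the
        # steady-state initial conditions the zero-phase procedure prescribes
        padlen = 3 * order
        head = y[1 : padlen + 1][::-1]
        tail = y[-padlen - 1 : -1][::-1]
        padded = np.concatenate([head, y, tail])
        zi = sps.lfilter_zi(b, a)
        fwd, _ = sps.lfilter(b, a, padded, zi=zi * padded[0])
        bwd, _ = sps.lfilter(b, a, fwd[::-1], zi=zi * fwd[-1])
        out = bwd[::-1]
        return out[padlen : padlen + len(y)]

    b, a = sps.butter(order, 35.0, btype="high", fs=rate)
    y = zero_phase(b, a, x)
    y = y - y.mean()
    y = np.maximum(0.0, y)
    b, a = sps.butter(order, 40.0, btype="low", fs=rate)
    return np.maximum(0.0, zero_phase(b, a, y))


class TestEmgChain:
    def test_constant_input_maps_to_zero(self):
        out = process_emg_trial(series(np.full(3000, 7.5)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-6 * 7.5)

    def test_zero_phase_burst_peak_not_shifted(self):
        n = 4000
        t = np.arange(n) / 1000.0
        # even-symmetric burst: Gaussian-windowed cosine carrier centered at 2 s
        burst = np.exp(-((t - 2.0) ** 2) / (2 * 0.05**2)) * np.cos(2 * np.pi * 80 * (t - 2.0))
        out = process_emg_trial(series(burst, t0=0.0))
        assert abs(int(out.values.argmax()) - 2000) <= 1

    def test_matches_independent_reference_filters(self, rng):
        x = rng.standard_normal(5000)
        out = process_emg_trial(series(x))
        np.testing.assert_allclose(out.values, reference_chain(x), atol=1e-9)

    def test_output_nonnegative_for_arbitrary_input(self, rng):
        for _ in range(5):
            x = rng.standard_normal(2000) * rng.uniform(0.1, 50)
            out = process_emg_trial(series(x))
            assert out.values.min() >= 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            process_emg_trial(series(np.ones(40)))


class TestEpoch:
    def test_paper_window_has_1400_samples_at_1khz(self):
        s = series(np.arange(2500.0), t0=-0.5, rate=1000.0)
        e = epoch(s)
        assert len(e) == 1400
        assert e.t0 == pytest.approx(-0.2)
        assert e.t_end < 1.2  # half-open

    def test_window_equal_to_extent_is_identity(self):
        s = series(np.arange(1400.0), t0=-0.2, rate=1000.0)
        e = epoch(s, EPOCH_WINDOW)
        np.testing.assert_array_equal(e.values, s.values)

    def test_missing_preonset_data_raises(self):
        s = series(np.arange(2000.0), t0=0.0, rate=1000.0)
        with pytest.raises(ValueError, match="does not cover"):
            epoch(s)


class TestNormalize:
    def test_shared_scale_across_trials(self):
        trials = [series([0.1, 0.2]), series([0.1, 0.5])]
        out = normalize_participant(trials)
        np.testing.assert_allclose(out[0].values, [0.2, 0.4])
        np.testing.assert_allclose(out[1].values, [0.2, 1.0])

    def test_idempotent_and_scale_invariant(self, rng):
        trials = [series(np.abs(rng.standard_normal(50))) for _ in range(3)]
        once = normalize_participant(trials)
        twice = normalize_participant(once)
        scaled = normalize_participant([t.with_values(7.3 * t.values) for t in trials])
        for a, b, c in zip(once, twice, scaled):
            np.testing.assert_allclose(a.values, b.values, atol=1e-15)
            np.testing.assert_allclose(a.values, c.values, atol=1e-12)

    def test_all_zero_set_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_participant([series(np.zeros(10))])


def toy_condition(n_trials, n_stepped, rng):
    emgs, coms = [], []
    for _ in range(n_trials):
        e = series(np.abs(rng.standard_normal(300)), t0=-0.1)
        mk = lambda: series(rng.standard_normal(300), t0=-0.1)
        emgs.append(e)
        coms.append(ComKinematics(mk(), mk(), mk()))
    stepped = [i < n_stepped for i in range(n_trials)]
    return emgs, coms, stepped


class TestAverageCondition:
    def test_mean_of_eight_nonstepped(self, rng):
        emgs, coms, stepped = toy_condition(8, 0, rng)
        avg = average_condition(emgs, coms, stepped)
        assert avg.n_trials == 8
        np.testing.assert_allclose(
            avg.emg.values, np.mean([e.values for e in emgs], axis=0), atol=1e-15
        )

    def test_six_stepped_of_eight_is_excluded(self, rng):
        emgs, coms, stepped = toy_condition(8, 6, rng)
        out = average_condition(emgs, coms, stepped, "P1", "forward", "large")
        assert isinstance(out, ExcludedCondition)
        assert out.n_nonstepped == 2

    def test_permutation_invariance(self, rng):
        emgs, coms, stepped = toy_condition(5, 0, rng)
        a = average_condition(emgs, coms, stepped)
        perm = [3, 1, 4, 0, 2]
        b = average_condition(
            [emgs[i] for i in perm], [coms[i] for i in perm], [stepped[i] for i in perm]
        )
        np.testing.assert_allclose(a.emg.values, b.emg.values, atol=1e-15)
        np.testing.assert_allclose(a.com.v.values, b.com.v.values, atol=1e-15)

    def test_grid_mismatch_rejected(self, rng):
        emgs, coms, stepped = toy_condition(3, 0, rng)
        emgs[1] = series(emgs[1].values, t0=0.0)
        with pytest.raises(ValueError, match="common grid"):
            average_condition(emgs, coms, stepped)


class TestComKinematicsHelpers:
    def test_velocity_of_ramp_is_its_slope(self):
        d = series(0.03 * np.arange(200) / 100.0, t0=0.0, rate=100.0)
        v = com_velocity(d)
        np.testing.assert_allclose(v.values[30:-30], 0.03, atol=1e-12)

    def test_velocity_of_constant_is_zero(self):
        v = com_velocity(series(np.full(120, 0.5), rate=100.0))
        np.testing.assert_allclose(v.values, 0.0, atol=1e-9)

    def test_sg_smoothing_preserves_cubics_in_the_interior(self):
        t = np.arange(300) / 100.0
        x = 0.2 * t**3 - 0.5 * t**2 + t
        smooth = savgol_filter(x, 49, 3)
        np.testing.assert_allclose(smooth[24:-24], x[24:-24], atol=1e-10)

    @pytest.mark.parametrize(
        "rate,rel_tol",
        [
            # 49-sample window = 49 ms at 1 kHz: negligible droop at 1 Hz
            (1000.0, 0.01),
            # at 100 Hz the window spans 0.48 s and attenuates 1 Hz by ~1.9%
            (100.0, 0.025),
        ],
    )
    def test_sinusoid_derivative_matches_analytic(self, rate, rel_tol):
        t = np.arange(int(3 * rate)) / rate
        d = series(np.sin(2 * np.pi * 1.0 * t), t0=0.0, rate=rate)
        v = com_velocity(d)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        mid = slice(len(t) // 6, 5 * len(t) // 6)
        err = np.abs(v.values[mid] - expected[mid]).max()
        assert err < rel_tol * np.abs(expected).max()

    def test_acceleration_is_force_over_mass(self):
        f = series(np.full(100, 80.0))
        np.testing.assert_allclose(com_acceleration(f, 80.0).values, 1.0)
        np.testing.assert_allclose(com_acceleration(f.with_values(f.values * 3), 80.0).values, 3.0)
        with pytest.raises(ValueError, match="mass"):
            com_acceleration(f, 0.0)

    def test_align_upsamples_ramp_exactly(self):
        t100 = np.arange(150) / 100.0 - 0.5
        mk100 = lambda s: UniformSeries(s * t100, -0.5, 100.0)
        com = ComKinematics(mk100(1.0), mk100(2.0), mk100(3.0))
        target = UniformSeries(np.zeros(1000), -0.45, 1000.0)
        out = cf.align_kinematics(com, target)
        np.testing.assert_allclose(out.d.values, target.t, atol=1e-12)
        np.testing.assert_allclose(out.v.values, 2 * target.t, atol=1e-12)

    def test_align_identity_when_grids_match(self, com_agonist):
        out = cf.align_kinematics(com_agonist, com_agonist.d)
        assert out.d is com_agonist.d

    @pytest.mark.parametrize(
        "freq,bound_rel",
        [
            (1.0, 1e-3),  # 1 Hz at 100 Hz: well under 0.1% of amplitude
            (2.0, (2 * np.pi * 2.0 / 100.0) ** 2 / 8),  # analytic (omega*h)^2/8 bound
        ],
    )
    def test_align_sinusoid_interp_error_within_analytic_bound(self, freq, bound_rel):
        rate_lo, amp = 100.0, 1.0
        t = np.arange(200) / rate_lo - 0.5
        x = amp * np.sin(2 * np.pi * freq * t)
        com = ComKinematics(
            UniformSeries(x, -0.5, rate_lo),
            UniformSeries(x.copy(), -0.5, rate_lo),
            UniformSeries(x.copy(), -0.5, rate_lo),
        )
        target = UniformSeries(np.zeros(1200), -0.4, 1000.0)
        out = cf.align_kinematics(com, target)
        exact = amp * np.sin(2 * np.pi * freq * target.t)
        assert np.abs(out.d.values - exact).max() < bound_rel * amp * 1.01

    def test_align_refuses_extrapolation(self):
        com = ComKinematics(
            UniformSeries(np.zeros(50), 0.0, 100.0),
            UniformSeries(np.zeros(50), 0.0, 100.0),
            UniformSeries(np.zeros(50), 0.0, 100.0),
        )
        target = UniformSeries(np.zeros(100), -0.2, 1000.0)
        with pytest.raises(ValueError, match="outside"):
            cf.align_kinematics(com, target)


class TestPeakExcursion:
    def test_sinusoid_amplitude(self):
        t = np.arange(1000) / 1000.0 - 0.2
        d = UniformSeries(0.03 * np.sin(2 * np.pi * 2 * t), -0.2, 1000.0)
        assert peak_excursion(d) == pytest.approx(0.03, rel=1e-4)

    def test_zero_trace(self):
        assert peak_excursion(UniformSeries(np.zeros(200), -0.05, 1000.0)) == 0.0

    def test_equals_brute_force_scan(self, com_agonist):
        d = com_agonist.d
        brute = max(abs(v) for v, t in zip(d.values, d.t) if t >= 0)
        assert peak_excursion(d) == pytest.approx(brute, abs=0.0)
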