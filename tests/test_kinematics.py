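"""Preprocessing chain: moduli, derivatives, filtering, segmentation,
anthropometric normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reachml import (
    SegmentationParams,
    TrajectoryRecording,
    anthropometric_reference,
    hand_speed,
    lowpass_zero_phase,
    modulus,
    normalize_recording,
    resting_baseline,
    segment_motion,
    two_point_derivative,
)
from reachml.errors import NoMotionError
from reachml.kinematics import NormalizationReference
from reachml.simulate import SENSORS

FS = 30.0


def segmentation_oracle(speed, params):
    """Exhaustive threshold-schedule scan; accept condition tested directly."""
    scale = speed.max() if params.relative_mode else 1.0
    theta0, dtheta = params.theta0 * scale, params.dtheta * scale
    schedule = []
    theta = theta0
    while theta > 0:
        schedule.append(theta)
        theta -= dtheta
    for k, theta in enumerate(schedule, start=1):
        above = np.nonzero(speed > theta)[0]
        if above.size == 0:
            continue
        s, e = int(above[0]), int(above[-1])
        sd_before = np.std(speed[:s]) if s > 0 else 0.0
        sd_after = np.std(speed[e + 1:]) if e < speed.size - 1 else 0.0
        if sd_before < theta and sd_after < theta:
            return s, e, True, k
    nz = np.nonzero(speed > 0)[0]
    return int(nz[0]), int(nz[-1]), False, len(schedule)


def random_speed_profile(rng):
    """Rest noise plus 1-3 smooth motion bumps of random width/height."""
    n = int(rng.integers(60, 200))
    speed = np.abs(rng.normal(0.0, rng.uniform(0.5, 3.0), n))
    for _ in range(int(rng.integers(1, 4))):
        centre = rng.uniform(0.2, 0.8) * n
        width = rng.uniform(0.05, 0.2) * n
        height = rng.uniform(20.0, 400.0)
        t = np.arange(n)
        speed += height * np.exp(-0.5 * ((t - centre) / width) ** 2)
    return speed


class TestModulus:
    @pytest.mark.parametrize(
        "xyz,expected",
        [((3.0, 4.0, 0.0), 5.0), ((0.0, 0.0, 0.0), 0.0), ((1.0, 2.0, 2.0), 3.0)],
    )
    def test_worked_examples(self, xyz, expected):
        series = np.tile(xyz, (4, 1))
        np.testing.assert_allclose(modulus(series), expected)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            modulus(np.zeros((5, 2)))


class TestTwoPointDerivative:
    def test_constant_series_gives_zeros(self):
        np.testing.assert_array_equal(
            two_point_derivative(np.full(10, 3.3), FS), np.zeros(10)
        )

    def test_linear_ramp_gives_ones(self):
        x = np.arange(20) / FS
        np.testing.assert_allclose(two_point_derivative(x, FS), 1.0)

    def test_stated_formula(self):
        np.testing.assert_array_equal(
            two_point_derivative(np.array([0.0, 1.0, 4.0, 9.0]), 1.0),
            [1.0, 1.0, 3.0, 5.0],
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            two_point_derivative(np.array([1.0]), FS)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    def test_linearity_and_length(self, values):
        x = np.array(values)
        d = two_point_derivative(x, FS)
        assert d.shape == x.shape
        np.testing.assert_allclose(
            two_point_derivative(2.0 * x, FS), 2.0 * d, rtol=1e-9, atol=1e-9
        )


class TestLowpassZeroPhase:
    def test_dc_gain_unity(self):
        const = np.full(100, 7.25)
        np.testing.assert_allclose(
            lowpass_zero_phase(const, FS), const, rtol=1e-9
        )

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        forward = lowpass_zero_phase(x, FS)
        reversed_ = lowpass_zero_phase(x[::-1], FS)[::-1]
        np.testing.assert_allclose(forward, reversed_, atol=1e-9)

    def test_passband_sinusoid_amplitude_matches_analytic_response(self):
        """0.5 Hz tone vs the squared Butterworth magnitude response."""
        f, fc, order = 0.5, 3.0, 4
        t = np.arange(300) / FS
        x = np.sin(2 * np.pi * f * t)
        y = lowpass_zero_phase(x, FS, fc, order)
        mid = slice(75, 225)
        # project on the quadrature pair to estimate the output amplitude
        basis = np.column_stack([np.sin(2 * np.pi * f * t[mid]), np.cos(2 * np.pi * f * t[mid])])
        coef, *_ = np.linalg.lstsq(basis, y[mid], rcond=None)
        measured = float(np.hypot(*coef))
        analytic = 1.0 / (1.0 + (f / fc) ** (2 * order))   # forward-backward
        assert abs(measured - analytic) < 0.01

    def test_too_short_and_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            lowpass_zero_phase(np.zeros(20), FS)
        with pytest.raises(ValueError):
            lowpass_zero_phase(np.zeros(100), FS, fc=15.0)

    def test_filter_then_differentiate_tracks_analytic_derivative(self):
        """Low-frequency sine: d/dt after the chain stays within 5% mid-signal."""
        f = 0.5
        t = np.arange(600) / FS
        x = np.sin(2 * np.pi * f * t)
        d = lowpass_zero_phase(
            two_point_derivative(lowpass_zero_phase(x, FS), FS), FS
        )
        analytic = 2 * np.pi * f * np.cos(2 * np.pi * f * (t - 0.5 / FS))
        mid = slice(150, 450)
        assert np.max(np.abs(d[mid] - analytic[mid])) < 0.05 * 2 * np.pi * f


class TestRestingBaseline:
    def test_constant(self):
        assert resting_baseline(np.full(30, 5.0)) == 5.0

    def test_first_and_last_blocks_only(self):
        x = np.concatenate([np.zeros(10), np.full(17, 99.0), np.full(10, 2.0)])
        assert resting_baseline(x) == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            resting_baseline(np.zeros(19))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_middle_samples(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = x.copy()
        y[10:-10] = rng.normal(scale=100.0, size=20)
        assert resting_baseline(x) == pytest.approx(resting_baseline(y))


class TestSegmentMotion:
    def test_zero_speed_raises_no_motion(self):
        with pytest.raises(NoMotionError):
            segment_motion(np.zeros(50))

    def test_noise_free_trapezoid(self):
        speed = np.zeros(220)
        speed[50:151] = 1.0
        result = segment_motion(speed, SegmentationParams(0.009, 0.001, True))
        assert (result.start_idx, result.end_idx) == (50, 150)
        assert result.converged
        assert result.iterations_used == 1

    def test_speed_above_threshold_everywhere(self):
        result = segment_motion(np.full(60, 4.0), SegmentationParams())
        assert (result.start_idx, result.end_idx) == (0, 59)
        assert result.converged

    def test_matches_exhaustive_oracle_on_random_profiles(self):
        rng = np.random.default_rng(7)
        params = SegmentationParams()
        for _ in range(50):
            speed = random_speed_profile(rng)
            result = segment_motion(speed, params)
            s, e, converged, iters = segmentation_oracle(speed, params)
            assert (result.start_idx, result.end_idx) == (s, e)
            assert result.converged == converged
            assert result.iterations_used == iters

    def test_detects_motion_inside_rest_padding(self, small_cohort):
        """Detected bounds fall inside the rest padding around true motion."""
        recordings, _ = small_cohort
        for rec in recordings[:20]:
            seg = segment_motion(hand_speed(rec))
            assert 0 <= seg.start_idx < seg.end_idx <= rec.n_samples - 1
            # the detected segment overlaps the true motion segment
            assert seg.start_idx < rec.true_offset_idx
            assert seg.end_idx > rec.true_onset_idx

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(theta0=0.0)
        with pytest.raises(ValueError):
            SegmentationParams(theta0=0.01, dtheta=0.02)


def _static_recording(hand, arm, shoulder, n=30, subject="S1"):
    positions = {
        "hand": np.tile(hand, (n, 1)).astype(float),
        "arm": np.tile(arm, (n, 1)).astype(float),
        "shoulder": np.tile(shoulder, (n, 1)).astype(float),
        "trunk": np.tile([0.0, 0.0, -100.0], (n, 1)),
    }
    return TrajectoryRecording(
        subject_id=subject, arm="R", target_label="CM", condition="healthy",
        fs=FS, timestamps=np.arange(n) / FS,
        positions=positions,
        angles={s: np.zeros((n, 3)) for s in SENSORS},
    )


class TestAnthropometricReference:
    def test_single_trial_component_and_limb_length(self):
        rec = _static_recording([0, 0, 0], [0, 0, 300], [0, 0, 600])
        ref = anthropometric_reference([rec])
        np.testing.assert_allclose(ref.components["hand_arm"], [0, 0, 300])
        assert ref.equivalent_limb_length == pytest.approx(600.0)

    def test_identical_trials_equal_single_trial(self):
        rec = _static_recording([0, 0, 0], [0, 0, 300], [0, 0, 600])
        one = anthropometric_reference([rec])
        two = anthropometric_reference([rec, rec])
        assert two.equivalent_limb_length == pytest.approx(one.equivalent_limb_length)
        np.testing.assert_allclose(
            two.components["arm_shoulder"], one.components["arm_shoulder"]
        )

    def test_limb_length_averaged_across_trials(self):
        a = _static_recording([0, 0, 0], [0, 0, 290], [0, 0, 580])
        b = _static_recording([0, 0, 0], [0, 0, 310], [0, 0, 620])
        ref = anthropometric_reference([a, b])
        assert ref.equivalent_limb_length == pytest.approx(600.0)

    def test_mixed_subjects_rejected(self):
        a = _static_recording([0, 0, 0], [0, 0, 300], [0, 0, 600], subject="S1")
        b = _static_recording([0, 0, 0], [0, 0, 300], [0, 0, 600], subject="S2")
        with pytest.raises(ValueError, match="subjects"):
            anthropometric_reference([a, b])


class TestNormalizeRecording:
    def _ref(self, length):
        return NormalizationReference(
            subject_id="S1",
            components={"hand_arm": np.zeros(3), "arm_shoulder": np.zeros(3),
                        "shoulder_trunk": np.zeros(3)},
            equivalent_limb_length=length,
            n_trials=1,
        )

    def test_positions_scaled_angles_unchanged(self, small_cohort):
        rec = small_cohort[0][0]
        norm = normalize_recording(rec, self._ref(500.0))
        np.testing.assert_allclose(
            norm.positions["hand"], rec.positions["hand"] / 500.0
        )
        np.testing.assert_array_equal(norm.angles["hand"], rec.angles["hand"])

    def test_unit_reference_is_identity(self, small_cohort):
        rec = small_cohort[0][0]
        norm = normalize_recording(rec, self._ref(1.0))
        np.testing.assert_array_equal(norm.positions["arm"], rec.positions["arm"])

    def test_scaled_twin_recordings_normalize_identically(self, healthy_profile, layout):
        """A geometrically x2 subject yields the same normalized trajectory."""
        from dataclasses import replace
        from reachml import simulate_trial

        rec = simulate_trial(healthy_profile, layout, "FM", "R", seed=4, noise=False)
        twin = replace(
            rec,
            positions={s: 2.0 * rec.positions[s] for s in SENSORS},
            angles={s: rec.angles[s].copy() for s in SENSORS},
            timestamps=rec.timestamps.copy(),
        )
        ref = anthropometric_reference([rec])
        twin_ref = anthropometric_reference([twin])
        assert twin_ref.equivalent_limb_length == pytest.approx(
            2.0 * ref.equivalent_limb_length
        )
        a = normalize_recording(rec, ref)
        b = normalize_recording(twin, twin_ref)
        np.testing.assert_allclose(
            a.positions["hand"], b.positions["hand"], atol=1e-9
        )

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            self._ref(0.0)
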