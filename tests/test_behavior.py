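"""Trajectory scoring: filters, rotation periods, response, corrections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from optomotor import (
    ArenaGeometry,
    StimulusCondition,
    Trajectory,
    apparent_wavelength,
    apply_exclusion_filters,
    assemble_tuning_curve,
    circling_direction,
    detect_rotation_periods,
    egocentric_correction,
    normalize_group,
    normalize_responses,
    onset_latency,
    pattern_speed_from_marker,
    response_from_periods,
    score_trajectory,
    SyntheticWalkSpec,
    generate_walk_trajectory,
)
from optomotor.behavior import _moving_average


def _circle_traj(omega_deg_s, duration=40.0, radius=5.0, frame_rate=60.0, phase=0.0):
    t = np.arange(0, duration, 1.0 / frame_rate)
    ang = np.radians(omega_deg_s) * t + phase
    return Trajectory(t=t, x=radius * np.cos(ang), y=radius * np.sin(ang))


def _brute_force_peaks(y, prominence):
    """Independent O(n^2) local-maximum + prominence oracle."""
    peaks = []
    for i in range(1, len(y) - 1):
        if y[i] > y[i - 1] and y[i] >= y[i + 1]:
            # prominence: climb down to the highest minimum separating this
            # peak from a higher one on each side
            left = y[:i][::-1]
            right = y[i + 1 :]
            prom_sides = []
            for side in (left, right):
                higher = np.nonzero(side > y[i])[0]
                segment = side[: higher[0]] if higher.size else side
                prom_sides.append(y[i] - segment.min() if segment.size else 0.0)
            higher_l = np.any(left > y[i])
            higher_r = np.any(right > y[i])
            if higher_l and higher_r:
                prom = min(prom_sides)
            else:
                prom = min(p for p, h in zip(prom_sides, (higher_l, higher_r))) if (higher_l or higher_r) else min(prom_sides)
            if prom >= prominence:
                peaks.append(i)
    return np.array(peaks)


class TestArena:
    def test_circumference(self):
        assert ArenaGeometry().drum_circumference_m == pytest.approx(0.597, abs=5e-4)

    def test_distance_bounds(self):
        a = ArenaGeometry()
        assert a.min_animal_pattern_distance == 80.0
        assert a.max_animal_pattern_distance == 110.0

    def test_bad_nesting_rejected(self):
        with pytest.raises(ValueError):
            ArenaGeometry(container_radius=80.0)

    def test_temporal_frequency_by_construction(self):
        c = StimulusCondition(wavelength=60.0, angular_velocity=210.0)
        assert c.temporal_frequency == pytest.approx(3.5)
        assert StimulusCondition(60.0, -210.0).direction == -1


class TestExclusionFilters:
    def test_wall_following_flagged(self):
        traj = generate_walk_trajectory(SyntheticWalkSpec(wall_follow_span=5.0, seed=1))
        assert apply_exclusion_filters(traj).exclusion_reasons == ["wall_following"]

    def test_short_walk_flagged(self):
        # walks ~8 s then rests for the remainder
        traj = generate_walk_trajectory(
            SyntheticWalkSpec(
                rest_fraction=0.88,
                onset_latency_mean=0.0,
                onset_latency_sd=0.0,
                seed=2,
            )
        )
        assert apply_exclusion_filters(traj).exclusion_reasons == ["short_walk"]

    def test_good_circling_retained(self):
        traj = generate_walk_trajectory(
            SyntheticWalkSpec(seed=5, position_noise_sd=0.1)
        )
        assert not apply_exclusion_filters(traj).excluded

    def test_rules_order_independent(self):
        # a path that trips both rules reports both reasons regardless of order
        traj = generate_walk_trajectory(
            SyntheticWalkSpec(
                wall_follow_span=5.0,
                rest_fraction=0.92,
                onset_latency_mean=0.0,
                onset_latency_sd=0.0,
                seed=3,
            )
        )
        reasons = apply_exclusion_filters(traj).exclusion_reasons
        assert set(reasons) == {"wall_following", "short_walk"}

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusion_filters(Trajectory(t=[], x=[], y=[]))


class TestRotationPeriods:
    def test_exact_circle_90_deg_s(self):
        seg = detect_rotation_periods(_circle_traj(90.0))
        np.testing.assert_allclose(seg.periods, 4.0, atol=1e-9)

    def test_fast_circle_quantization_bound(self):
        seg = detect_rotation_periods(_circle_traj(360.0))
        assert np.all(np.abs(seg.periods - 1.0) <= 1.0 / 60 + 1e-9)

    def test_straight_path_flags_no_rotation(self):
        t = np.arange(0, 20, 1 / 60)
        seg = detect_rotation_periods(Trajectory(t=t, x=0.3 * t, y=0.1 * t))
        assert seg.no_rotation and seg.periods.size == 0

    def test_matches_brute_force_peak_oracle(self, noisy_walk):
        smoothing, prominence = 0.25, 1.0
        seg = detect_rotation_periods(noisy_walk, smoothing, prominence)
        w = max(1, int(round(smoothing * noisy_walk.frame_rate)))
        ys = _moving_average(noisy_walk.y, w)
        oracle = _brute_force_peaks(ys, prominence)
        got = np.searchsorted(noisy_walk.t, seg.peak_times)
        np.testing.assert_array_equal(np.sort(got), np.sort(oracle))

    def test_noisy_circle_period_within_5_percent(self, noisy_walk):
        seg = detect_rotation_periods(noisy_walk)
        truth = 360.0 / noisy_walk.ground_truth["turning_velocity"]
        assert np.mean(seg.periods) == pytest.approx(truth, rel=0.05)


class TestResponse:
    def test_direct_substitution(self):
        seg = detect_rotation_periods(_circle_traj(180.0))
        m = response_from_periods(seg, 1)
        assert m.response == pytest.approx(180.0, rel=1e-6)

    def test_counter_directional_sign(self):
        seg = detect_rotation_periods(_circle_traj(360.0))
        m = response_from_periods(seg, -1)
        assert m.response == pytest.approx(-360.0, rel=0.02)

    def test_no_periods_gives_absent_response(self):
        t = np.arange(0, 20, 1 / 60)
        seg = detect_rotation_periods(Trajectory(t=t, x=0.3 * t, y=0.1 * t))
        assert response_from_periods(seg) is None

    def test_circling_direction_signs(self):
        assert circling_direction(_circle_traj(90.0)) == 1
        assert circling_direction(_circle_traj(-90.0)) == -1

    def test_synthetic_recovery_within_5_percent(self, noisy_walk):
        m = score_trajectory(noisy_walk)
        assert m.response == pytest.approx(120.0, rel=0.05)

    def test_signed_recovery(self):
        traj = generate_walk_trajectory(
            SyntheticWalkSpec(turning_velocity=-180.0, seed=3)
        )
        m = score_trajectory(traj)
        assert m.response == pytest.approx(-180.0, rel=0.02)

    def test_quantization_bound_on_clean_circles(self):
        for omega in (90.0, 180.0, 360.0):
            m = score_trajectory(_circle_traj(omega, duration=30.0))
            period = 360.0 / omega
            # one frame of quantization on the mean period
            bound = omega * (1 / 60) / period
            assert abs(m.response - omega) <= bound + 1e-9


class TestNormalization:
    def test_direct_division(self):
        np.testing.assert_allclose(
            normalize_group([90.0, 180.0, -45.0]), [0.5, 1.0, -0.25]
        )

    def test_singleton(self):
        np.testing.assert_allclose(normalize_group([123.0]), [1.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_group([0.0, 0.0])

    @given(
        values=st.lists(
            st.floats(-500, 500).filter(lambda v: abs(v) > 1e-6), min_size=2, max_size=8
        ),
        scale=st.floats(0.1, 50.0),
    )
    def test_idempotent_scale_invariant_preserves_argmax(self, values, scale):
        v = np.asarray(values)
        n1 = normalize_group(v)
        np.testing.assert_allclose(normalize_group(n1), n1, atol=1e-12)
        np.testing.assert_allclose(normalize_group(scale * v), n1, atol=1e-9)
        assert np.argmax(n1) == np.argmax(v)
        assert np.all(np.sign(n1) == np.sign(v))
        assert np.max(np.abs(n1)) <= 1.0 + 1e-12

    def test_grouped_table(self):
        df = pd.DataFrame(
            {
                "experiment": ["a", "a", "a", "b", "b"],
                "response": [90.0, 180.0, -45.0, 0.0, 0.0],
            }
        )
        out = normalize_responses(df)
        np.testing.assert_allclose(
            out.loc[out.experiment == "a", "normalized"], [0.5, 1.0, -0.25]
        )
        assert out.loc[out.experiment == "b", "normalized_undefined"].all()


class TestEgocentricCorrection:
    def test_printed_endpoints(self):
        assert apparent_wavelength(15.0, 80.0) == pytest.approx(17.8, abs=0.05)
        assert apparent_wavelength(15.0, 110.0) == pytest.approx(13.0, abs=0.05)

    def test_identity_at_center(self):
        assert apparent_wavelength(15.0, 95.0) == pytest.approx(15.0)

    def test_trajectory_correction(self):
        t = np.arange(0, 10, 1 / 60)
        traj = Trajectory(t=t, x=np.full_like(t, 15.0), y=np.zeros_like(t))
        cond = StimulusCondition(15.0, 210.0)
        corr = egocentric_correction(traj, cond)
        assert corr.mean_distance_from_center == pytest.approx(15.0)
        assert corr.wavelength_near == pytest.approx(17.8, abs=0.05)
        assert corr.wavelength_far == pytest.approx(13.0, abs=0.05)
        assert corr.nominal is cond


class TestPatternSpeed:
    def test_direct_substitution(self):
        ang = np.arange(1200 + 1) * (3600.0 / 1200)  # 10 turns in 1200 frames
        assert pattern_speed_from_marker(ang) == pytest.approx(360.0, rel=0.001)

    def test_half_speed(self):
        ang = np.arange(2400 + 1) * (3600.0 / 2400)
        assert pattern_speed_from_marker(ang) == pytest.approx(180.0, rel=0.001)

    def test_forward_simulated_drum_inverted_within_quantization(self):
        speed = 296.0
        frames = np.arange(0, 3000)
        ang = speed * frames / 120.0
        got = pattern_speed_from_marker(ang)
        n_frames = int(np.ceil(10 * 360.0 / (speed / 120.0)))
        quantization = abs(10 * 360.0 / (n_frames / 120.0) - speed) + 0.5
        assert abs(got - speed) <= quantization

    def test_insufficient_rotations_reports_achieved_count(self):
        ang = np.arange(0, 200) * 1.0
        with pytest.raises(ValueError, match="rotations"):
            pattern_speed_from_marker(ang, n_rotations=10)


class TestOnsetLatency:
    @pytest.mark.parametrize("noise", [0.0, 0.2])
    def test_generator_latency_detected(self, noise):
        for seed in (0, 7, 13):
            traj = generate_walk_trajectory(
                SyntheticWalkSpec(
                    position_noise_sd=noise,
                    onset_latency_mean=1.76,
                    onset_latency_sd=0.0,
                    seed=seed,
                )
            )
            lat = onset_latency(traj, 0.0)
            assert lat == pytest.approx(1.76, abs=0.25)

    def test_circling_from_start_has_near_zero_latency(self):
        traj = generate_walk_trajectory(
            SyntheticWalkSpec(onset_latency_mean=0.0, onset_latency_sd=0.0, seed=4)
        )
        assert onset_latency(traj, 0.0) == pytest.approx(0.0, abs=0.15)

    def test_never_circles_gives_absent(self):
        t = np.arange(0, 30, 1 / 60)
        traj = Trajectory(t=t, x=0.2 * t - 3, y=0.1 * t - 2)
        assert onset_latency(traj, 0.0) is None


class TestTuningCurveAssembly:
    def test_single_and_replicated_conditions(self):
        df = pd.DataFrame(
            {
                "wavelength": [60.0, 60.0, 60.0, 45.0],
                "velocity": [210.0, 210.0, 210.0, 150.0],
                "normalized": [1.0, 1.0, 1.0, 0.8],
            }
        )
        curve = assemble_tuning_curve(df)
        row60 = curve[curve.velocity == 210.0].iloc[0]
        assert row60["mean"] == 1.0 and row60["sd"] == 0.0 and row60["n"] == 3
        row45 = curve[curve.velocity == 150.0].iloc[0]
        assert row45["sd"] == 0.0 and row45["n"] == 1
        assert row60["temporal_frequency"] == pytest.approx(3.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assemble_tuning_curve(pd.DataFrame(columns=["wavelength", "velocity", "normalized"]))
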