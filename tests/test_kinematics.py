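import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuttlekin.errors import DegenerateGeometryError, InsufficientDataError
from cuttlekin.kinematics import (
    body_axis,
    club_angle,
    eye_angle,
    horizontal_speed,
    signed_angle,
    target_distance,
    tentacle_angle,
    visual_attack_angle,
)

finite = st.floats(-1e6, 1e6, allow_nan=False)
nonzero_vec = st.tuples(finite, finite).filter(lambda v: math.hypot(*v) > 1e-6)


class TestSignedAngle:
    @pytest.mark.parametrize(
        "u, v, expected",
        [((1, 0), (0, 1), 90.0), ((3, 4), (3, 4), 0.0), ((1, 0), (1, 1), 45.0),
         ((1, 0), (-1, 0), 180.0), ((0, 1), (1, 0), -90.0)],
    )
    def test_known_angles(self, u, v, expected):
        assert signed_angle(u, v) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(u=nonzero_vec, v=nonzero_vec)
    def test_antisymmetric_and_in_range(self, u, v):
        a = signed_angle(u, v)
        b = signed_angle(v, u)
        assert -180.0 < a <= 180.0
        if not math.isclose(abs(a), 180.0, abs_tol=1e-6):
            assert a == pytest.approx(-b, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(u=nonzero_vec, v=nonzero_vec)
    def test_matches_atan2_difference_oracle(self, u, v):
        """Independent oracle: difference of absolute polar angles, wrapped."""
        expected = math.degrees(math.atan2(v[1], v[0]) - math.atan2(u[1], u[0]))
        expected = (expected + 180.0) % 360.0 - 180.0
        if expected == -180.0:
            expected = 180.0
        got = signed_angle(u, v)
        assert math.isclose(got, expected, abs_tol=1e-9) or math.isclose(
            abs(got), 180.0, abs_tol=1e-9
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            signed_angle((0, 0), (1, 0))


class TestBodyAxis:
    def test_construction(self):
        head, heading, ml = body_axis((10, -2), (10, 2), (0, 0))
        np.testing.assert_allclose(head, [10, 0])
        np.testing.assert_allclose(heading, [1, 0], atol=1e-12)
        assert ml == pytest.approx(10.0)

    def test_rigid_motion_equivariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            le, re, me = rng.uniform(-100, 100, (3, 2))
            if np.allclose(0.5 * (le + re), me):
                continue
            _, h0, ml0 = body_axis(le, re, me)
            phi = rng.uniform(0, 2 * np.pi)
            # rotation acting in the y-up frame, expressed on image coords
            flip = np.array([1.0, -1.0])
            rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
            t = rng.uniform(-50, 50, 2)
            tf = lambda p: (rot @ (np.asarray(p) * flip) + t) * flip
            _, h1, ml1 = body_axis(tf(le), tf(re), tf(me))
            assert ml1 == pytest.approx(ml0)
            assert signed_angle(h0, h1) == pytest.approx(np.degrees(phi) % 360 - (360 if np.degrees(phi) % 360 > 180 else 0), abs=1e-6)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            body_axis((0, -2), (0, 2), (0, 0))

    def test_recovers_simulated_heading_under_noise(self, noisy_trial):
        scenario, track, truth, res = noisy_trial
        est = np.degrees(
            np.arctan2(res.kinematics.frame["heading_y"], res.kinematics.frame["heading_x"])
        )
        true = truth.frame["heading_deg"].to_numpy()
        err = np.abs((est - true + 180) % 360 - 180)
        assert np.median(err) < 0.5
        assert np.quantile(err, 0.95) < 1.0


class TestAttackAngle:
    def test_prey_on_heading_ray(self):
        assert visual_attack_angle((0, 0), (1, 0), (5, 0)) == pytest.approx(0.0)

    def test_prey_quarter_turn_ccw(self):
        # image coords: prey straight above the head is +90 in the y-up frame
        assert visual_attack_angle((0, 0), (1, 0), (0, -5)) == pytest.approx(90.0)

    def test_matches_two_point_trig_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            head = rng.uniform(-500, 500, 2)
            prey = rng.uniform(-500, 500, 2)
            if np.allclose(head, prey):
                continue
            phi = rng.uniform(-np.pi, np.pi)
            heading = np.array([np.cos(phi), np.sin(phi)])
            # oracle: wrap difference between prey bearing (y-up) and heading angle
            bearing = math.atan2(-(prey[1] - head[1]), prey[0] - head[0])
            expected = math.degrees(bearing - phi)
            expected = (expected + 180) % 360 - 180
            got = visual_attack_angle(head, heading, prey)
            if abs(expected) != 180.0:
                assert got == pytest.approx(expected, abs=1e-9)

    def test_mirror_antisymmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            head = rng.uniform(0, 2048, 2)
            prey = rng.uniform(0, 2048, 2)
            phi = rng.uniform(-np.pi, np.pi)
            heading = np.array([np.cos(phi), np.sin(phi)])
            a = visual_attack_angle(head, heading, prey)
            mirror = lambda p: np.array([2048 - p[0], p[1]])
            b = visual_attack_angle(mirror(head), np.array([-heading[0], heading[1]]), mirror(prey))
            if abs(a) != 180.0:
                assert b == pytest.approx(-a, abs=1e-9)

    def test_prey_at_head_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            visual_attack_angle((1, 1), (1, 0), (1, 1))


class TestEyeAndTentacleAngles:
    def test_symmetric_eyes_have_opposite_beta(self):
        heading = np.array([1.0, 0.0])
        bl = eye_angle((0, 0), heading, (10, -2))
        br = eye_angle((0, 0), heading, (10, 2))
        assert bl == pytest.approx(-br)
        assert bl > 0  # left eye above the axis in image coords -> CCW

    def test_eye_on_axis(self):
        assert eye_angle((0, 0), (1.0, 0.0), (10, 0)) == pytest.approx(0.0)

    def test_vergence_shift_appears_as_delta_beta(self):
        """Rotating an eye point 2 degrees toward the axis changes beta by 2."""
        mantle = np.array([0.0, 0.0])
        heading = np.array([1.0, 0.0])
        r, base = 10.0, 20.0  # eye at 20 deg off-axis (y-up), 10 px from mantle end
        eye0 = np.array([r * np.cos(np.radians(base)), -r * np.sin(np.radians(base))])
        eye1 = np.array([r * np.cos(np.radians(base - 2)), -r * np.sin(np.radians(base - 2))])
        shift = eye_angle(mantle, heading, eye0) - eye_angle(mantle, heading, eye1)
        assert shift == pytest.approx(2.0, abs=1e-9)

    def test_tentacle_straight_ahead(self):
        assert tentacle_angle((0, 0), (1.0, 0.0), (30, 0)) == pytest.approx(0.0)

    def test_tentacle_at_thirty_degrees(self):
        tip = np.array([30 * np.cos(np.radians(30)), -30 * np.sin(np.radians(30))])
        assert tentacle_angle((0, 0), (1.0, 0.0), tip) == pytest.approx(30.0)


class TestClubAngle:
    def test_tip_moving_along_tentacle_axis(self):
        n = 11
        head = np.zeros((n, 2))
        tip = np.stack([10.0 + np.arange(n), np.zeros(n)], axis=1)
        theta = club_angle(head, tip, window=5)
        np.testing.assert_allclose(theta[2:-2], 0.0, atol=1e-9)

    def test_tip_moving_perpendicular(self):
        n = 11
        y = np.arange(n, dtype=float)
        head = np.stack([np.zeros(n), y], axis=1)
        tip = np.stack([np.full(n, 10.0), y], axis=1)  # axis fixed at +x, motion in +y image
        theta = club_angle(head, tip, window=5)
        np.testing.assert_allclose(np.abs(theta[2:-2]), 90.0, atol=1e-9)

    def test_stationary_tip_undefined(self):
        n = 9
        head = np.zeros((n, 2))
        tip = np.tile([10.0, 0.0], (n, 1))
        assert np.isnan(club_angle(head, tip, window=5)).all()


class TestSpeedAndDistance:
    def test_stationary_target_zero_speed(self):
        v = horizontal_speed(np.full(50, 123.4), fps=90, mm_per_px=0.5)
        np.testing.assert_allclose(v, 0.0, atol=1e-9)

    def test_constant_velocity_exact_when_noise_free(self):
        # 40 mm/s at 90 fps, 0.5 mm/px -> 8/9 px per frame
        x = np.arange(100) * (40.0 / 90.0 / 0.5)
        v = horizontal_speed(x, fps=90, mm_per_px=0.5, window=5)
        np.testing.assert_allclose(v, 40.0, atol=1e-9)

    def test_noisy_mean_within_two_percent(self):
        rng = np.random.default_rng(21)
        v_true = 25.0
        x = np.arange(2000) * (v_true / 90.0 / 0.5) + rng.normal(0, 1.0, 2000)
        v = horizontal_speed(x, fps=90, mm_per_px=0.5, window=5)
        assert abs(v.mean() - v_true) / v_true < 0.02

    def test_too_few_frames(self):
        with pytest.raises(InsufficientDataError):
            horizontal_speed(np.array([1.0, 2.0]), fps=90, mm_per_px=0.5)

    @pytest.mark.parametrize(
        "prey_offset_mm, expected_ml", [(80.0, 1.6), (0.0, 0.0), (50.0, 1.0)]
    )
    def test_target_distance_arithmetic(self, prey_offset_mm, expected_ml):
        mm_per_px = 0.5
        head = np.array([0.0, 0.0])
        prey = np.array([prey_offset_mm / mm_per_px, 0.0])
        assert target_distance(head, prey, mantle_scale_px=100.0) == pytest.approx(expected_ml)
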