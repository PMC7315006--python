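import numpy as np
import pandas as pd
import pytest

import cuttlekin.kinematics as kin_mod
from cuttlekin.errors import ScenarioError
from cuttlekin.pipeline import analyze_track
from cuttlekin.pose_io import read_dlc_csv
from cuttlekin.simulate import (
    SimScenario,
    StrikeCommand,
    make_dataset,
    simulate_cuttlefish,
    simulate_prey,
    simulate_trial,
)


class TestPreyRig:
    def test_commanded_speeds_exact(self):
        s = SimScenario(seed=0, duration_s=60.0)
        prey = simulate_prey(s)
        v = prey["prey_v_mm_s"].to_numpy()
        phase = prey["prey_phase"].to_numpy()
        assert np.abs(v[phase == "slow"]).mean() == pytest.approx(25.0)
        assert np.abs(v[phase == "fast"]).mean() == pytest.approx(75.0)

    def test_position_bounded_by_rail(self):
        s = SimScenario(seed=0, duration_s=120.0)
        x = simulate_prey(s)["prey_x_mm"].to_numpy()
        assert x.min() >= 0.0 and x.max() <= s.rail_span_mm

    def test_leg_durations_follow_span_over_speed(self):
        s = SimScenario(seed=0, duration_s=40.0)
        phase = simulate_prey(s)["prey_phase"].to_numpy()
        # slow leg: 250 mm at 25 mm/s = 10 s = 900 frames
        first_fast = np.argmax(phase == "fast")
        assert first_fast == pytest.approx(900, abs=2)


class TestPursuitAgent:
    def test_velocity_gains_applied_per_phase(self, clean_trial):
        scenario, track, truth, _ = clean_trial
        tf = truth.frame
        v_agent = np.gradient(tf["cutt_x_mm"].to_numpy()) * scenario.fps
        sel = tf["attention"].to_numpy()
        # skip a delay margin after each phase change when checking the gain
        phase = tf["prey_phase"].to_numpy()
        steady = np.r_[[False] * 20, phase[20:] == phase[:-20]]
        slow = sel & steady & (phase == "slow")
        fast = sel & steady & (phase == "fast")
        assert np.abs(v_agent[slow]).mean() == pytest.approx(0.9 * 25.0, rel=0.05)
        assert np.abs(v_agent[fast]).mean() == pytest.approx(0.05 * 75.0, rel=0.25)

    def test_alpha_collapses_within_attention(self, clean_trial):
        scenario, track, truth, res = clean_trial
        alpha = res.kinematics.frame["alpha_deg"].to_numpy()
        att = truth.frame["attention"].to_numpy()
        inside = att.copy()
        inside[: int(6 * scenario.fps)] = False  # allow the orienting saccade
        assert np.nanmax(np.abs(alpha[inside])) < 30.0
        assert np.nanmedian(np.abs(alpha[~att])) > 60.0

    def test_predictive_strike_on_slow_prey_succeeds(self):
        # attention from t=0 keeps the prey within tentacle reach at the strike
        s = SimScenario(seed=1, duration_s=20.0, attention_schedule=((0.0, 20.0),),
                        strikes=(StrikeCommand(time_s=8.0, predictive=True),))
        _, truth = simulate_trial(s)
        assert truth.frame["prey_phase"].iloc[int(8.0 * s.fps)] == "slow"
        assert bool(truth.strikes.loc[0, "success"])

    def test_nonpredictive_strike_on_fast_prey_fails(self):
        # the ~11 mm aim error from the uncompensated 150 ms delay at 75 mm/s
        # exceeds the 5 mm capture radius
        s = SimScenario(seed=1, duration_s=20.0, attention_schedule=((0.0, 20.0),),
                        strikes=(StrikeCommand(time_s=11.0, predictive=False),))
        _, truth = simulate_trial(s)
        assert truth.frame["prey_phase"].iloc[int(11.0 * s.fps)] == "fast"
        assert not bool(truth.strikes.loc[0, "success"])

    def test_nonpredictive_slow_miss_equals_delay_plus_travel_lag(self):
        # uncompensated 150 ms delay plus ~85 ms tentacle travel at 25 mm/s
        # puts the club ~6 mm behind the prey: prediction is needed even for
        # slow prey
        s = SimScenario(seed=1, duration_s=20.0, attention_schedule=((0.0, 20.0),),
                        strikes=(StrikeCommand(time_s=8.0, predictive=False),))
        _, truth = simulate_trial(s)
        assert truth.strikes.loc[0, "miss_mm"] == pytest.approx(5.9, abs=1.5)
        assert not bool(truth.strikes.loc[0, "success"])

    def test_strike_outside_attention_rejected(self):
        s = SimScenario(seed=1, duration_s=20.0, attention_schedule=((5.0, 15.0),),
                        strikes=(StrikeCommand(time_s=17.0),))
        with pytest.raises(ScenarioError):
            simulate_cuttlefish(s, simulate_prey(s))

    def test_strike_time_outside_trial_rejected(self):
        with pytest.raises(ValueError):
            SimScenario(seed=1, duration_s=20.0, strikes=(StrikeCommand(time_s=25.0),))

    def test_strike_bearing_recovered_as_delta(self, clean_trial):
        """Mean tentacle angle over the strike matches the commanded aim bearing."""
        scenario, track, truth, res = clean_trial
        fps = scenario.fps
        row = truth.strikes.iloc[0]
        k0 = int(row["onset_s"] * fps)
        k_peak = int(row["peak_s"] * fps)
        k_mid = (k0 + k_peak) // 2  # once extended well clear of the head
        kin = res.kinematics.frame
        delta = kin["delta_left_deg"].to_numpy()[k_mid:k_peak]
        heading = truth.frame["heading_deg"].to_numpy()[k_mid:k_peak]
        expected = (row["aimed_bearing_deg"] - heading + 180) % 360 - 180
        assert np.nanmean(np.abs(delta - expected)) < 2.0

    def test_terminal_correction_visible_in_club_angle(self):
        s = SimScenario(seed=6, duration_s=20.0, noise_sigma_px=0.0, occlusion_prob=0.0,
                        strikes=(StrikeCommand(time_s=8.0, terminal_correction_deg=20.0),))
        track, truth = simulate_trial(s)
        res = analyze_track(track)
        fps = s.fps
        row = truth.strikes.iloc[0]
        theta = res.kinematics.frame["theta_left_deg"].to_numpy()
        k_peak = int(row["peak_s"] * fps)
        early = np.nanmean(np.abs(theta[int(row["onset_s"] * fps) + 3 : k_peak - 5]))
        final = np.nanmax(np.abs(theta[k_peak - 5 : k_peak + 1]))
        assert final - early >= 15.0


class TestRendering:
    def test_noise_free_rendering_inverts_exactly(self, clean_trial):
        scenario, track, truth, res = clean_trial
        est = np.degrees(np.arctan2(res.kinematics.frame["heading_y"],
                                    res.kinematics.frame["heading_x"]))
        err = np.abs((est - truth.frame["heading_deg"].to_numpy() + 180) % 360 - 180)
        assert err.max() < 1e-6

    def test_prey_reference_matches_truth_exactly_when_noise_free(self, clean_trial):
        scenario, track, truth, res = clean_trial
        prey_px = kin_mod.prey_reference(res.clean)
        x_mm = prey_px[:, 0] * scenario.mm_per_px
        np.testing.assert_allclose(x_mm, truth.frame["prey_x_mm"].to_numpy(), atol=1e-6)

    def test_occlusion_fraction_within_binomial_band(self):
        s = SimScenario(seed=13, duration_s=120.0, occlusion_prob=0.1)
        track, _ = simulate_trial(s)
        lik = track.data.loc[:, (slice(None), "likelihood")].to_numpy()
        frac = (lik < 0.9).mean()
        n_draws = lik.size
        assert abs(frac - 0.1) < 2.58 * np.sqrt(0.1 * 0.9 / n_draws) + 1e-4

    def test_same_seed_bit_identical(self):
        s = SimScenario(seed=77, duration_s=5.0, attention_schedule=((0.0, 5.0),))
        a, _ = simulate_trial(s)
        b, _ = simulate_trial(s)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seeds_differ(self):
        s1 = SimScenario(seed=1, duration_s=5.0, attention_schedule=((0.0, 5.0),))
        s2 = SimScenario(seed=2, duration_s=5.0, attention_schedule=((0.0, 5.0),))
        a, _ = simulate_trial(s1)
        b, _ = simulate_trial(s2)
        assert not np.allclose(a.data.to_numpy(), b.data.to_numpy())


class TestDatasetFiles:
    def test_default_frame_count(self, tmp_path):
        s = SimScenario(seed=0, duration_s=10.0, attention_schedule=((0.0, 10.0),))
        pose_path, truth_path, scenario_path = make_dataset(s, tmp_path)
        track = read_dlc_csv(pose_path, s.metadata())
        assert track.n_frames == 900
        truth = pd.read_csv(truth_path)
        assert len(truth) == 900  # frame-aligned

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            SimScenario(seed=0, duration_s=0.0)

    def test_two_seeds_same_schema_different_data(self, tmp_path):
        paths = {}
        for seed in (1, 2):
            s = SimScenario(seed=seed, duration_s=5.0, attention_schedule=((0.0, 5.0),))
            paths[seed] = make_dataset(s, tmp_path)
        h1 = paths[1][0].read_text().splitlines()[:3]
        h2 = paths[2][0].read_text().splitlines()[:3]
        assert h1 == h2  # identical header schema
        assert paths[1][0].read_text() != paths[2][0].read_text()

    def test_files_cross_reference(self, tmp_path):
        import yaml

        s = SimScenario(seed=4, duration_s=5.0, attention_schedule=((0.0, 5.0),))
        pose_path, truth_path, scenario_path = make_dataset(s, tmp_path)
        meta = yaml.safe_load(scenario_path.read_text())
        assert meta["files"]["pose"] == pose_path.name
        assert meta["files"]["truth"] == truth_path.name
        assert meta["scenario"]["seed"] == 4
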