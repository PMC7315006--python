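"""Ground-truthed synthetic trials emulating the prey-rig experiment.

The rig moves a hooked shrimp along a 1-D rail: slowly (ca. 25 mm/s) in
one direction, then suddenly reversing and moving fast (ca. 75 mm/s) in
the other, for a 120 s session recorded at 90 fps. The simulated
cuttlefish is a pursuit agent with a sensorimotor delay: during
scripted attention windows it orients toward the prey (saccadic turn,
then rate-limited tracking) and matches the delayed prey velocity
scaled by a phase-specific gain — high in the slow leg, near zero in
the fast leg, encoding the empirical finding that cuttlefish keep up
only with slowly moving prey. Commanded tentacular strikes extend the
club tips ballistically toward either the delayed observed prey
position or a position extrapolated by the delay (visual prediction),
optionally rotating the club bearing over the final 30% of the
extension (terminal closed-loop correction).

Every simulated quantity is logged as ground truth, and the rendered
pose track adds Gaussian landmark noise, plus gross displacement and
low confidence on occluded points, so parameter-recovery tests can
score the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from cuttlekin.errors import ScenarioError
from cuttlekin.pose_io import (
    ALL_PARTS,
    BodyPart,
    PoseTrack,
    TrialMetadata,
    make_pose_frame,
    write_dlc_csv,
)

RAIL_Y_FRACTION = 0.65  # rail height as a fraction of the world (image) height
EYE_HALFWIDTH_ML = 0.12  # cuttlefish eye lateral offset, fraction of mantle length
REST_EXTENSION_ML = 0.15  # retracted club tips sit between the arms
TIP_LATERAL_ML = 0.05  # lateral separation of the paired tips
SHRIMP_EYE_HALFWIDTH_MM = 1.5
SHRIMP_HOOK_OFFSET_MM = (2.0, 3.0)
SHRIMP_TAIL_OFFSET_MM = (-18.0, 0.0)
SUCCESS_RADIUS_MM = 5.0  # order of a shrimp body width; a simulator choice
SACCADE_THRESHOLD_DEG = 20.0
OCCLUSION_DISPLACEMENT_PX = 80.0  # gross mislabel amplitude for occluded points


class StrikeCommand(BaseModel):
    """One commanded tentacular strike."""

    time_s: float
    predictive: bool = True
    terminal_correction_deg: float = 0.0
    duration_ms: float = 120.0
    peak_extension_ml: float = 1.8


class SimScenario(BaseModel):
    """Parameters of one synthetic trial.

    Defaults follow the experimental protocol: 120 s sessions at 90 fps,
    prey legs of 25 mm/s (leftward) and 75 mm/s (rightward) with
    instantaneous reversals, a sub-adult-sized mantle (80 mm), and 0.5
    mm/px calibration placing the tank in a 2048 px frame. Pursuit gains
    (0.9 slow, 0.05 fast) encode that the agent keeps up with slow prey
    and freezes during the fast leg.
    """

    seed: int = 0
    duration_s: float = 120.0
    fps: float = 90.0
    rail_span_mm: float = 250.0
    v_slow_mm_s: float = 25.0  # leftward leg
    v_fast_mm_s: float = 75.0  # rightward leg
    mantle_len_mm: float = 80.0
    mm_per_px: float = 0.5
    frame_size: tuple[int, int] = (2048, 2048)
    pursuit_gain_slow: float = Field(0.9, ge=0.0, le=1.0)
    pursuit_gain_fast: float = Field(0.05, ge=0.0, le=1.0)
    sensorimotor_delay_ms: float = 150.0
    turn_rate_max_deg_s: float = 90.0
    saccade_rate_deg_s: float = 600.0
    standoff_mm: float = 100.0  # initial head distance below the rail
    attention_schedule: Literal["auto"] | tuple[tuple[float, float], ...] = "auto"
    strikes: tuple[StrikeCommand, ...] = ()
    noise_sigma_px: float = 1.0
    occlusion_prob: float = Field(0.02, ge=0.0, lt=1.0)

    @model_validator(mode="after")
    def _check(self) -> "SimScenario":
        for name in ("duration_s", "fps", "rail_span_mm", "v_slow_mm_s", "v_fast_mm_s",
                     "mantle_len_mm", "mm_per_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for cmd in self.strikes:
            if not 0 <= cmd.time_s < self.duration_s:
                raise ValueError(f"strike at {cmd.time_s} s outside the trial")
        return self

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def delay_frames(self) -> int:
        return int(round(self.sensorimotor_delay_ms / 1000.0 * self.fps))

    def windows(self) -> list[tuple[float, float]]:
        """Resolved attention windows (seconds)."""
        if self.attention_schedule != "auto":
            return [tuple(w) for w in self.attention_schedule]
        if self.duration_s > 12.0:
            return [(5.0, self.duration_s - 5.0)]
        return [(0.0, self.duration_s)]

    def metadata(self, animal_id: str = "sim", trial_id: str | None = None) -> TrialMetadata:
        return TrialMetadata(
            animal_id=animal_id,
            trial_id=trial_id if trial_id is not None else f"seed{self.seed}",
            fps=self.fps,
            mm_per_px=self.mm_per_px,
            frame_size=self.frame_size,
            session_length_s=self.duration_s,
        )


@dataclass
class GroundTruth:
    """Frame-aligned true state plus the strike log.

    ``frame`` columns (all world mm, y-up): time_s, prey_x_mm,
    prey_v_mm_s (commanded), prey_phase, cutt_x_mm, cutt_y_mm,
    heading_deg, attention, tip_left_x_mm/.._y_mm, tip_right_x_mm/.._y_mm,
    ext_ml. ``strikes`` has one row per commanded strike with realized
    aim, timing and success.
    """

    scenario: SimScenario
    frame: pd.DataFrame
    strikes: pd.DataFrame
    rail_y_mm: float

    @property
    def n_frames(self) -> int:
        return len(self.frame)


def simulate_prey(s: SimScenario) -> pd.DataFrame:
    """Triangle-wave prey trajectory with the phase command log.

    The prey starts at the right end of the rail moving leftward at the
    slow speed; at each rail end it reverses instantaneously into the
    other leg. Columns: time_s, prey_x_mm, prey_v_mm_s (commanded
    velocity for the step starting at that frame), prey_phase.
    """
    if s.rail_span_mm <= 0:
        raise ScenarioError("rail span must be > 0")
    n = s.n_frames
    dt = 1.0 / s.fps
    x = np.empty(n)
    v = np.empty(n)
    phase = np.empty(n, dtype=object)
    pos = s.rail_span_mm
    vel, lab = -s.v_slow_mm_s, "slow"
    for k in range(n):
        x[k] = pos
        v[k] = vel
        phase[k] = lab
        pos += vel * dt
        if pos <= 0.0:
            pos = 0.0
            vel, lab = s.v_fast_mm_s, "fast"
        elif pos >= s.rail_span_mm:
            pos = s.rail_span_mm
            vel, lab = -s.v_slow_mm_s, "slow"
    return pd.DataFrame(
        {"time_s": np.arange(n) / s.fps, "prey_x_mm": x, "prey_v_mm_s": v, "prey_phase": phase}
    )


def _attention_mask(s: SimScenario) -> np.ndarray:
    mask = np.zeros(s.n_frames, dtype=bool)
    for a, b in s.windows():
        mask[int(round(a * s.fps)) : int(round(b * s.fps)) + 1] = True
    return mask


def _unit(deg: float | np.ndarray) -> np.ndarray:
    rad = np.radians(deg)
    return np.stack([np.cos(rad), np.sin(rad)], axis=-1)


def simulate_cuttlefish(s: SimScenario, prey: pd.DataFrame) -> GroundTruth:
    """Run the pursuit agent against a simulated prey trajectory.

    During attention windows the agent's horizontal velocity is the
    delayed commanded prey velocity scaled by the phase gain, and its
    heading turns toward the prey (saccade rate when more than 20
    degrees off, tracking rate otherwise) so the visual attack angle
    collapses shortly after each window opens. Outside attention it sits
    still, heading 90 degrees off the prey bearing. Strikes must fall
    inside attention windows.
    """
    n = s.n_frames
    dt = 1.0 / s.fps
    fps = s.fps
    prey_x = prey["prey_x_mm"].to_numpy()
    prey_v = prey["prey_v_mm_s"].to_numpy()
    prey_phase = prey["prey_phase"].to_numpy()
    attention = _attention_mask(s)

    windows = s.windows()
    for cmd in s.strikes:
        if not any(a <= cmd.time_s <= b for a, b in windows):
            raise ScenarioError(f"strike at {cmd.time_s} s outside every attention window")

    world_h_mm = s.frame_size[1] * s.mm_per_px
    world_w_mm = s.frame_size[0] * s.mm_per_px
    rail_y = RAIL_Y_FRACTION * world_h_mm
    rail_x0 = 0.5 * (world_w_mm - s.rail_span_mm)  # rail centered in the frame

    gains = {"slow": s.pursuit_gain_slow, "fast": s.pursuit_gain_fast, "stationary": 0.0}
    delay = s.delay_frames

    cx = np.empty(n)
    cy = np.full(n, rail_y - s.standoff_mm)
    hdg = np.empty(n)

    pos_x = rail_x0 + prey_x[0]  # start under the prey's initial position
    bearing0 = _bearing(pos_x, cy[0], rail_x0 + prey_x[0], rail_y)
    heading = bearing0 + 90.0 if not attention[0] else bearing0
    for k in range(n):
        cx[k] = pos_x
        hdg[k] = heading
        kd = max(0, k - delay)
        if attention[k]:
            vx = gains[str(prey_phase[kd])] * prey_v[kd]
            target = _bearing(pos_x, cy[k], rail_x0 + prey_x[k], rail_y)
        else:
            vx = 0.0
            target = _bearing(pos_x, cy[k], rail_x0 + prey_x[k], rail_y) + 90.0
        err = _wrap(target - heading)
        rate = s.saccade_rate_deg_s if abs(err) > SACCADE_THRESHOLD_DEG else s.turn_rate_max_deg_s
        heading = heading + np.clip(err, -rate * dt, rate * dt)
        heading = _wrap(heading)
        # tank walls: a velocity-matching tracker drifts over long sessions
        pos_x = float(np.clip(pos_x + vx * dt, 0.05 * world_w_mm, 0.95 * world_w_mm))

    # --- tentacle tips ------------------------------------------------
    ml = s.mantle_len_mm
    ext = np.full(n, REST_EXTENSION_ML)
    tip_bearing = hdg.copy()  # retracted tips point along the body axis
    tip_anchor = np.stack([cx, cy], axis=1).copy()
    strike_rows = []
    for cmd in s.strikes:
        k0 = int(round(cmd.time_s * fps))
        dur = max(1, int(round(cmd.duration_ms / 1000.0 * fps)))
        k_peak = min(n - 1, k0 + dur)
        k_end = min(n - 1, k0 + 2 * dur)
        kd = max(0, k0 - delay)
        obs_x = prey_x[kd]
        if cmd.predictive:
            aim_x = obs_x + (s.sensorimotor_delay_ms / 1000.0) * prey_v[kd]
        else:
            aim_x = obs_x
        aim_world = np.array([rail_x0 + aim_x, rail_y])
        head0 = np.array([cx[k0], cy[k0]])
        base_bearing = np.degrees(np.arctan2(*(aim_world - head0)[::-1]))

        up = np.linspace(REST_EXTENSION_ML, cmd.peak_extension_ml, k_peak - k0 + 1)
        ext[k0 : k_peak + 1] = np.maximum(ext[k0 : k_peak + 1], up)
        down = np.linspace(cmd.peak_extension_ml, REST_EXTENSION_ML, k_end - k_peak + 1)
        ext[k_peak : k_end + 1] = np.maximum(ext[k_peak : k_end + 1], down)

        # terminal correction: club bearing rotates over the last 30% of
        # the extension ramp and holds through retraction
        brg = np.full(k_end - k0 + 1, base_bearing)
        n_corr = max(1, int(round(0.3 * dur)))
        c0 = (k_peak - k0) - n_corr
        ramp = np.linspace(0.0, cmd.terminal_correction_deg, n_corr + 1)
        brg[c0 : c0 + n_corr + 1] += ramp
        brg[c0 + n_corr + 1 :] += cmd.terminal_correction_deg
        tip_bearing[k0 : k_end + 1] = brg
        # the ejected tentacles travel to a fixed world target: anchor the
        # strike ray at the head's onset position, not the moving head
        tip_anchor[k0 : k_end + 1] = head0

        # success: the club pair passes within the capture radius of the
        # (moving) prey at some instant of the sweep; fine-sampled because
        # the radial tip speed is ~10 mantle lengths per second
        t_fine = np.linspace(k0, k_end, 20 * (k_end - k0) + 1)
        e_fine = np.interp(t_fine, np.arange(k0, k_end + 1), ext[k0 : k_end + 1])
        b_fine = np.interp(t_fine, np.arange(k0, k_end + 1), brg)
        tip_fine = head0 + e_fine[:, None] * ml * _unit(b_fine)
        prey_fine = np.stack(
            [rail_x0 + np.interp(t_fine, np.arange(n), prey_x), np.full_like(t_fine, rail_y)],
            axis=1,
        )
        miss_mm = float(np.linalg.norm(tip_fine - prey_fine, axis=1).min())
        success = miss_mm <= SUCCESS_RADIUS_MM
        strike_rows.append(
            dict(
                onset_s=k0 / fps,
                peak_s=k_peak / fps,
                end_s=k_end / fps,
                aim_x_mm=aim_x,
                aimed_bearing_deg=base_bearing,
                predictive=cmd.predictive,
                terminal_correction_deg=cmd.terminal_correction_deg,
                peak_extension_ml=cmd.peak_extension_ml,
                miss_mm=miss_mm,
                success=success,
            )
        )

    u_tip = _unit(tip_bearing)
    perp = np.stack([-u_tip[:, 1], u_tip[:, 0]], axis=1)
    tip_l = tip_anchor + ext[:, None] * ml * u_tip + TIP_LATERAL_ML * ml * perp
    tip_r = tip_anchor + ext[:, None] * ml * u_tip - TIP_LATERAL_ML * ml * perp

    frame = pd.DataFrame(
        {
            "time_s": prey["time_s"].to_numpy(),
            "prey_x_mm": rail_x0 + prey_x,
            "prey_v_mm_s": prey_v,
            "prey_phase": prey_phase,
            "cutt_x_mm": cx,
            "cutt_y_mm": cy,
            "heading_deg": hdg,
            "attention": attention,
            "tip_left_x_mm": tip_l[:, 0],
            "tip_left_y_mm": tip_l[:, 1],
            "tip_right_x_mm": tip_r[:, 0],
            "tip_right_y_mm": tip_r[:, 1],
            "ext_ml": ext,
        }
    )
    strikes = pd.DataFrame(
        strike_rows,
        columns=[
            "onset_s", "peak_s", "end_s", "aim_x_mm", "aimed_bearing_deg",
            "predictive", "terminal_correction_deg", "peak_extension_ml",
            "miss_mm", "success",
        ],
    )
    return GroundTruth(scenario=s, frame=frame, strikes=strikes, rail_y_mm=rail_y)


def _bearing(x0: float, y0: float, x1: float, y1: float) -> float:
    return float(np.degrees(np.arctan2(y1 - y0, x1 - x0)))


def _wrap(deg):
    """Wrap to (-180, 180]."""
    out = (np.asarray(deg) + 180.0) % 360.0 - 180.0
    out = np.where(np.isclose(out, -180.0), 180.0, out)
    return float(out) if out.ndim == 0 else out


def render_poses(s: SimScenario, truth: GroundTruth) -> PoseTrack:
    """Render the true state into a noisy image-coordinate pose track.

    World coordinates (mm, y-up) map to image pixels with a y flip.
    Visible points get Gaussian noise of ``noise_sigma_px`` and
    likelihood in [0.95, 1]; occluded points (independent Bernoulli
    draws) are displaced grossly — emulating confident mislabels the
    likelihood gate must catch — and get likelihood in [0, 0.5].
    Deterministic for a given seed.
    """
    tf = truth.frame
    n = len(tf)
    ml = s.mantle_len_mm
    head = np.stack([tf["cutt_x_mm"].to_numpy(), tf["cutt_y_mm"].to_numpy()], axis=1)
    u = _unit(tf["heading_deg"].to_numpy())
    perp = np.stack([-u[:, 1], u[:, 0]], axis=1)
    prey = np.stack([tf["prey_x_mm"].to_numpy(), np.full(n, truth.rail_y_mm)], axis=1)
    rail = np.array([1.0, 0.0])
    rail_perp = np.array([0.0, 1.0])

    world: dict[BodyPart, np.ndarray] = {
        BodyPart.LEFT_EYE: head + EYE_HALFWIDTH_ML * ml * perp,
        BodyPart.RIGHT_EYE: head - EYE_HALFWIDTH_ML * ml * perp,
        BodyPart.MANTLE_END: head - ml * u,
        BodyPart.LEFT_CLUB_TIP: np.stack(
            [tf["tip_left_x_mm"].to_numpy(), tf["tip_left_y_mm"].to_numpy()], axis=1
        ),
        BodyPart.RIGHT_CLUB_TIP: np.stack(
            [tf["tip_right_x_mm"].to_numpy(), tf["tip_right_y_mm"].to_numpy()], axis=1
        ),
        BodyPart.SHRIMP_LEFT_EYE: prey + SHRIMP_EYE_HALFWIDTH_MM * rail_perp,
        BodyPart.SHRIMP_RIGHT_EYE: prey - SHRIMP_EYE_HALFWIDTH_MM * rail_perp,
        BodyPart.SHRIMP_HOOK: prey + np.array(SHRIMP_HOOK_OFFSET_MM),
        BodyPart.SHRIMP_TAIL: prey + np.array(SHRIMP_TAIL_OFFSET_MM),
    }

    rng = np.random.default_rng([s.seed, 0xC0FFEE])
    world_h_px = s.frame_size[1]
    data = make_pose_frame(n)
    for part in ALL_PARTS:
        pts = world[part] / s.mm_per_px
        x_px = pts[:, 0]
        y_px = world_h_px - pts[:, 1]  # image convention: y down
        occluded = rng.random(n) < s.occlusion_prob
        if s.noise_sigma_px > 0:
            x_px = x_px + rng.normal(0.0, s.noise_sigma_px, n)
            y_px = y_px + rng.normal(0.0, s.noise_sigma_px, n)
        shift = rng.uniform(-OCCLUSION_DISPLACEMENT_PX, OCCLUSION_DISPLACEMENT_PX, (n, 2))
        x_px = np.where(occluded, x_px + shift[:, 0], x_px)
        y_px = np.where(occluded, y_px + shift[:, 1], y_px)
        lik = np.where(
            occluded, rng.uniform(0.0, 0.5, n), rng.uniform(0.95, 1.0, n)
        )
        data[(part.value, "x")] = x_px
        data[(part.value, "y")] = y_px
        data[(part.value, "likelihood")] = lik
    return PoseTrack(metadata=s.metadata(), data=data)


def simulate_trial(s: SimScenario) -> tuple[PoseTrack, GroundTruth]:
    """Prey + agent + rendering in one call."""
    prey = simulate_prey(s)
    truth = simulate_cuttlefish(s, prey)
    track = render_poses(s, truth)
    return track, truth


def make_dataset(s: SimScenario, outdir: str | Path) -> tuple[Path, Path, Path]:
    """Write one synthetic trial to disk.

    Emits the pose CSV (DeepLabCut dialect), the frame-aligned
    ground-truth CSV, and the scenario (with the realized strike log) as
    a YAML file, cross-referenced by a scenario id derived from the
    seed.
    """
    if s.duration_s <= 0:
        raise ScenarioError("zero-duration scenario")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = f"sim-seed{s.seed}"
    track, truth = simulate_trial(s)
    pose_path = write_dlc_csv(track, outdir / f"{sid}_pose.csv")
    truth_path = outdir / f"{sid}_truth.csv"
    truth.frame.to_csv(truth_path, index_label="frame", float_format="%.6f")
    scenario_path = outdir / f"{sid}_scenario.yaml"
    payload = {
        "scenario_id": sid,
        "scenario": s.model_dump(mode="json"),
        "strike_log": truth.strikes.to_dict(orient="records"),
        "files": {"pose": pose_path.name, "truth": truth_path.name},
    }
    scenario_path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return pose_path, truth_path, scenario_path
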