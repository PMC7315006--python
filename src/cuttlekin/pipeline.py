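"""End-to-end composition: raw pose track -> kinematics -> events.

Thin glue used by the CLI, the examples and the acceptance machinery;
all scientific content lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass

from cuttlekin.cleaning import CleanTrack, clean
from cuttlekin.config import PipelineConfig
from cuttlekin.kinematics import KinematicSeries, compute_kinematics
from cuttlekin.pose_io import PoseTrack
from cuttlekin.segmentation import (
    Episode,
    PreyPhase,
    StrikeEvent,
    classify_prey_phase,
    detect_attention_episodes,
    detect_strikes,
)


@dataclass
class TrialAnalysis:
    """Everything the pipeline derives from one trial."""

    clean: CleanTrack
    kinematics: KinematicSeries
    phase: PreyPhase
    episodes: list[Episode]
    strikes: list[StrikeEvent]


def analyze_track(track: PoseTrack, config: PipelineConfig | None = None) -> TrialAnalysis:
    """Run cleaning, kinematics, prey-phase labeling and event detection."""
    cfg = config or PipelineConfig()
    ct = clean(
        track,
        likelihood_threshold=cfg.cleaning.likelihood_threshold,
        jump_gate_px=cfg.cleaning.jump_gate_px,
        smoothing_window=cfg.cleaning.smoothing_window,
    )
    kin = compute_kinematics(ct)
    phase = classify_prey_phase(
        kin.frame["prey_speed_mm_s"].to_numpy(),
        fps=kin.metadata.fps,
        v_split=cfg.phases.v_split_mm_s,
        v_still=cfg.phases.v_still_mm_s,
    )
    episodes = detect_attention_episodes(
        kin,
        alpha_max=cfg.segmentation.alpha_max_deg,
        t_min=cfg.segmentation.t_min_s,
        gap_max=cfg.segmentation.gap_max_s,
    )
    strikes = detect_strikes(
        kin,
        e_on=cfg.segmentation.e_on_ml,
        v_on=cfg.segmentation.v_on_ml_s,
        phase=phase,
    )
    return TrialAnalysis(clean=ct, kinematics=kin, phase=phase, episodes=episodes, strikes=strikes)
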