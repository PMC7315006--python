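"""Segmentation of trials into behavioral phases and events.

The visual attack has three sequential phases: attention (the animal
turns to face the prey and aligns its body axis with it), positioning
(range adjustment, interleaved with attention for moving prey) and
seizure (the ballistic tentacular strike). Attention is operationalised
here purely from body alignment — sustained intervals of small visual
attack angle alpha — because that is the classical behavioural
definition; the thresholds are exposed and documented as a
reconstruction. Strikes are detected from tentacle extension in mantle
lengths. Strike success is never inferred from kinematics (contact
cannot be resolved from five labeled points); it comes from simulator
ground truth or an annotation column.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from cuttlekin.errors import ParameterError
from cuttlekin.kinematics import KinematicSeries

# prey-phase speed thresholds (mm/s): below v_still the prey is parked,
# between the thresholds it is in the slow leg (~25 mm/s), above in the
# fast leg (~75 mm/s)
DEFAULT_V_STILL = 5.0
DEFAULT_V_SPLIT = 50.0

# attention-episode reconstruction defaults
DEFAULT_ALPHA_MAX = 30.0  # deg
DEFAULT_T_MIN = 1.0  # s
DEFAULT_GAP_MAX = 0.5  # s

# strike detection defaults
DEFAULT_E_ON = 0.5  # ML, extension onset threshold
DEFAULT_V_ON = 2.0  # ML/s, minimum extension rate at onset
BILATERAL_MERGE_S = 0.1  # tentacles are shot as a pair

PHASE_LABELS = ("stationary", "slow", "fast")


@dataclass
class PreyPhase:
    """Per-frame prey motion phase and the reversal times.

    ``labels`` holds one of {stationary, slow, fast} per frame;
    ``reversal_times_s`` are the instants where the commanded velocity
    flips sign between the slow and fast legs.
    """

    labels: np.ndarray
    reversal_times_s: list[float]
    fps: float

    def label_at(self, t_s: float) -> str:
        i = int(np.clip(round(t_s * self.fps), 0, len(self.labels) - 1))
        return str(self.labels[i])


@dataclass
class Episode:
    """One attention episode: a sustained interval of body-axis alignment."""

    start_s: float
    end_s: float
    strike_attempt: bool = False
    strike_success: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError("episode needs 0 <= start < end")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class StrikeEvent:
    """One tentacular strike (seizure event) with its derived metrics."""

    onset_s: float
    end_s: float
    peak_extension_ml: float
    strike_angle_deg: float
    delta_beta_left_deg: float
    delta_beta_right_deg: float
    prey_phase_at_onset: str | None = None
    time_since_reversal_s: float = float("inf")
    success: bool | None = None


def classify_prey_phase(
    prey_speed_mm_s: np.ndarray,
    fps: float,
    v_split: float = DEFAULT_V_SPLIT,
    v_still: float = DEFAULT_V_STILL,
) -> PreyPhase:
    """Label every frame stationary / slow / fast from the prey speed.

    |v| < v_still is stationary, v_still <= |v| < v_split slow,
    |v| >= v_split fast. Labels are median-filtered over 5 frames to
    suppress single-frame flicker at the speed thresholds. Reversals are
    the sign changes of the velocity between moving (slow or fast)
    frames.
    """
    if v_still >= v_split:
        raise ParameterError("need v_still < v_split")
    v = np.asarray(prey_speed_mm_s, dtype=float)
    mag = np.abs(v)
    codes = np.where(mag >= v_split, 2, np.where(mag >= v_still, 1, 0))
    if len(codes) >= 5:
        codes = median_filter(codes, size=5, mode="nearest")
    labels = np.array(PHASE_LABELS, dtype=object)[codes]

    moving = codes > 0
    idx = np.flatnonzero(moving)
    reversal_times: list[float] = []
    if idx.size:
        signs = np.sign(v[idx])
        # compress into constant-sign runs; a reversal needs both
        # neighbouring runs to persist >= 3 frames, which rejects sign
        # flicker from the noisier speed estimates at the series edges
        bounds = np.flatnonzero(np.diff(signs) != 0) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(signs)]])
        lengths = ends - starts
        for r in range(1, len(starts)):
            if lengths[r - 1] >= 3 and lengths[r] >= 3 and signs[starts[r]] * signs[starts[r - 1]] < 0:
                reversal_times.append(float(idx[starts[r]] / fps))
    return PreyPhase(labels=labels, reversal_times_s=reversal_times, fps=fps)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [first, last] index runs of True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def detect_attention_episodes(
    kin: KinematicSeries,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    t_min: float = DEFAULT_T_MIN,
    gap_max: float = DEFAULT_GAP_MAX,
) -> list[Episode]:
    """Maximal intervals with |alpha| <= alpha_max, gap-merged and length-filtered.

    Interruptions shorter than ``gap_max`` seconds are merged; episodes
    shorter than ``t_min`` seconds are dropped. Returned episodes are
    disjoint and time-ordered.
    """
    if alpha_max <= 0 or t_min < 0 or gap_max < 0:
        raise ParameterError("alpha_max > 0 and t_min, gap_max >= 0 required")
    fps = kin.metadata.fps
    alpha = kin.frame["alpha_deg"].to_numpy()
    aligned = np.abs(alpha) <= alpha_max  # NaN compares False
    runs = _runs(aligned)
    # merge runs separated by fewer than gap_max seconds of misalignment
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and (a - merged[-1][1] - 1) / fps < gap_max:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    episodes = []
    for a, b in merged:
        start, end = a / fps, b / fps
        if end - start >= t_min:
            episodes.append(Episode(start_s=start, end_s=end))
    return episodes


def detect_strikes(
    kin: KinematicSeries,
    e_on: float = DEFAULT_E_ON,
    v_on: float = DEFAULT_V_ON,
    phase: PreyPhase | None = None,
) -> list[StrikeEvent]:
    """Detect tentacular strikes from club-tip extension.

    For each side the normalized extension e(t) = |club_tip - head| in
    mantle lengths is thresholded: an event starts where e crosses
    ``e_on`` upward with de/dt >= ``v_on`` and lasts until e falls back
    below ``e_on``. Left/right detections whose onsets fall within 100 ms
    are merged (the tentacles are shot as a pair). Delta-beta is the
    max - min excursion of each eye angle over [onset - 0.5 s, end].
    """
    fps = kin.metadata.fps
    if kin.mantle_scale_px <= 0:
        raise ParameterError("mantle scale undefined")
    raw_events: list[tuple[int, int, float]] = []
    for side in ("left", "right"):
        e = kin.frame[f"ext_{side}_ml"].to_numpy()
        rate = np.gradient(e) * fps
        above = e >= e_on
        onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        for i in onsets:
            if rate[i] < v_on:
                continue
            below = np.flatnonzero(~above[i:])
            j = (i + below[0] - 1) if below.size else (len(e) - 1)
            raw_events.append((int(i), int(j), float(np.nanmax(e[i : j + 1]))))

    raw_events.sort()
    events: list[StrikeEvent] = []
    merged_raw: list[list] = []
    for i, j, peak in raw_events:
        if merged_raw and (i - merged_raw[-1][0]) / fps <= BILATERAL_MERGE_S:
            merged_raw[-1][1] = max(merged_raw[-1][1], j)
            merged_raw[-1][2] = max(merged_raw[-1][2], peak)
        else:
            merged_raw.append([i, j, peak])

    alpha = kin.frame["alpha_deg"].to_numpy()
    for i, j, peak in merged_raw:
        w0 = max(0, i - int(round(0.5 * fps)))
        d_beta = {}
        for side in ("left", "right"):
            beta = kin.frame[f"beta_{side}_deg"].to_numpy()[w0 : j + 1]
            beta = beta[~np.isnan(beta)]
            d_beta[side] = float(beta.max() - beta.min()) if beta.size else float("nan")
        ev = StrikeEvent(
            onset_s=i / fps,
            end_s=j / fps,
            peak_extension_ml=peak,
            strike_angle_deg=float(alpha[i]),
            delta_beta_left_deg=d_beta["left"],
            delta_beta_right_deg=d_beta["right"],
        )
        if phase is not None:
            lab, dt = strike_timing(ev, phase)
            ev = replace(ev, prey_phase_at_onset=lab, time_since_reversal_s=dt)
        events.append(ev)
    return events


@dataclass
class VelocityPair:
    """Per-trial mean |cuttlefish speed| during slow vs fast prey motion,
    restricted to attention-episode frames. A missing phase within the
    episodes leaves that member None and excludes the trial from the
    paired test."""

    mean_slow_mm_s: float | None
    mean_fast_mm_s: float | None

    @property
    def complete(self) -> bool:
        return self.mean_slow_mm_s is not None and self.mean_fast_mm_s is not None


def paired_velocity_summary(
    kin: KinematicSeries, phase: PreyPhase, episodes: list[Episode]
) -> VelocityPair:
    """Mean absolute cuttlefish horizontal speed split by prey phase."""
    if not episodes:
        raise ParameterError("paired_velocity_summary needs >= 1 attention episode")
    fps = kin.metadata.fps
    n = kin.n_frames
    in_attention = np.zeros(n, dtype=bool)
    for ep in episodes:
        a = int(round(ep.start_s * fps))
        b = int(round(ep.end_s * fps))
        in_attention[a : b + 1] = True
    speed = np.abs(kin.frame["cutt_speed_mm_s"].to_numpy())
    means = {}
    for lab in ("slow", "fast"):
        sel = in_attention & (phase.labels == lab)
        means[lab] = float(speed[sel].mean()) if sel.any() else None
    return VelocityPair(mean_slow_mm_s=means["slow"], mean_fast_mm_s=means["fast"])


def strike_timing(strike: StrikeEvent, phase: PreyPhase) -> tuple[str, float]:
    """Prey phase at strike onset and seconds since the last reversal.

    Returns an infinite sentinel when no reversal precedes the onset.
    """
    label = phase.label_at(strike.onset_s)
    before = [t for t in phase.reversal_times_s if t <= strike.onset_s]
    dt = strike.onset_s - before[-1] if before else float("inf")
    return label, float(dt)


def episodes_to_frame(
    episodes: list[Episode], animal: str = "", trial: str = ""
) -> pd.DataFrame:
    """Tidy episode table, schema-compatible with the packaged summary table."""
    return pd.DataFrame(
        {
            "animal": animal,
            "trial": trial,
            "attempt": [e.strike_attempt for e in episodes],
            "success": [e.strike_success for e in episodes],
            "duration_s": [e.duration_s for e in episodes],
            "pre_strike": [e.strike_attempt for e in episodes],
            "start_s": [e.start_s for e in episodes],
            "end_s": [e.end_s for e in episodes],
        }
    )


def strikes_to_frame(strikes: list[StrikeEvent]) -> pd.DataFrame:
    """Tidy strike-event table."""
    return pd.DataFrame(
        {
            "onset_s": [s.onset_s for s in strikes],
            "end_s": [s.end_s for s in strikes],
            "peak_extension_ml": [s.peak_extension_ml for s in strikes],
            "strike_angle_deg": [s.strike_angle_deg for s in strikes],
            "delta_beta_left_deg": [s.delta_beta_left_deg for s in strikes],
            "delta_beta_right_deg": [s.delta_beta_right_deg for s in strikes],
            "prey_phase_at_onset": [s.prey_phase_at_onset for s in strikes],
            "time_since_reversal_s": [s.time_since_reversal_s for s in strikes],
            "success": [s.success for s in strikes],
        }
    )
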