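"""Per-frame kinematic variables of the visual attack.

All inputs are image coordinates (origin top-left, y downward) as pose
tools emit them; every angle is computed in a y-up mathematical frame,
so positive angles are counter-clockwise when the video is viewed
normally. Angles are reported in degrees in (-180, 180].

Variables
---------
alpha
    Visual attack angle: bearing of the prey from the cuttlefish head,
    relative to the anterior-posterior body axis. Zero means the animal
    faces the prey.
beta (left/right)
    Eye angle: direction of each eye point from the mantle end, relative
    to the body axis. Its excursion (delta-beta) proxies eye vergence,
    since only one labeled point per eye exists.
delta (left/right)
    Tentacular strike angle: direction of each tentacle club tip from
    the head, relative to the body axis. Defined only while the tentacle
    is extended.
theta (left/right)
    Tentacle club angle: direction of the club tip's motion relative to
    the head-to-tip (tentacle) axis. A terminal change in theta is the
    signature of closed-loop strike correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cuttlekin.cleaning import CleanTrack, smooth
from cuttlekin.errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    ParameterError,
)
from cuttlekin.pose_io import BodyPart, TrialMetadata

#: below this fraction of the mantle length the clubs sit between the
#: arms and the tip label carries no directional information
EXTENSION_THRESHOLD_ML = 0.35

#: minimum tip displacement (px) over the club-angle window for the club
#: direction to be considered defined
CLUB_MIN_DISPLACEMENT_PX = 2.0


def _yup(points: np.ndarray) -> np.ndarray:
    """Flip image coordinates to the y-up mathematical frame."""
    pts = np.asarray(points, dtype=float).copy()
    pts[..., 1] *= -1.0
    return pts


def _angle_or_nan(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Signed CCW angle (deg) from u to v, NaN where either vector vanishes.

    Vectors are already in the y-up frame.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = u[..., 0] * v[..., 0] + u[..., 1] * v[..., 1]
    ang = np.degrees(np.arctan2(cross, dot))
    # atan2 returns (-180, 180]; force -180 -> 180 for the half-open range
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    zero = (np.linalg.norm(u, axis=-1) == 0) | (np.linalg.norm(v, axis=-1) == 0)
    return np.where(zero, np.nan, ang)


def signed_angle(u, v) -> float | np.ndarray:
    """Counter-clockwise angle from ``u`` to ``v`` in degrees, in (-180, 180].

    Vectors are in the y-up mathematical frame. Antisymmetric except at
    exactly 180 degrees. Raises on zero-length input.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(np.linalg.norm(u, axis=-1) == 0) or np.any(np.linalg.norm(v, axis=-1) == 0):
        raise DegenerateGeometryError("signed_angle of zero-length vector")
    ang = _angle_or_nan(u, v)
    return float(ang) if ang.ndim == 0 else ang


def body_axis(
    left_eye: np.ndarray, right_eye: np.ndarray, mantle_end: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Head point, heading unit vector and mantle length from three landmarks.

    The head is the eye midpoint (image px); the heading points from the
    mantle end toward the head, returned as a unit vector in the y-up
    frame; the mantle length is |head - mantle_end| in px. Vectorized
    over leading axes.
    """
    left_eye = np.asarray(left_eye, dtype=float)
    right_eye = np.asarray(right_eye, dtype=float)
    mantle_end = np.asarray(mantle_end, dtype=float)
    head = 0.5 * (left_eye + right_eye)
    axis = _yup(head) - _yup(mantle_end)
    length = np.linalg.norm(axis, axis=-1)
    if np.any(length == 0):
        raise DegenerateGeometryError("mantle_end coincident with head")
    heading = axis / length[..., None]
    return head, heading, length


def visual_attack_angle(
    head: np.ndarray, heading: np.ndarray, prey_ref: np.ndarray
) -> float | np.ndarray:
    """Alpha: signed angle from the body axis to the head-to-prey direction.

    ``head`` and ``prey_ref`` are image px; ``heading`` is the y-up unit
    vector from :func:`body_axis`.
    """
    to_prey = _yup(prey_ref) - _yup(head)
    if np.any(np.linalg.norm(to_prey, axis=-1) == 0):
        raise DegenerateGeometryError("prey reference coincident with head")
    return signed_angle(heading, to_prey)


def eye_angle(
    mantle_end: np.ndarray, heading: np.ndarray, eye_point: np.ndarray
) -> float | np.ndarray:
    """Beta: signed angle from the body axis to the mantle-end-to-eye direction."""
    to_eye = _yup(eye_point) - _yup(mantle_end)
    if np.any(np.linalg.norm(to_eye, axis=-1) == 0):
        raise DegenerateGeometryError("eye coincident with mantle_end")
    return signed_angle(heading, to_eye)


def tentacle_angle(
    head: np.ndarray, heading: np.ndarray, club_tip: np.ndarray
) -> float | np.ndarray:
    """Delta: signed angle from the body axis to the head-to-club-tip direction."""
    to_tip = _yup(club_tip) - _yup(head)
    if np.any(np.linalg.norm(to_tip, axis=-1) == 0):
        raise DegenerateGeometryError("club tip coincident with head")
    return signed_angle(heading, to_tip)


def club_angle(
    head: np.ndarray,
    club_tip: np.ndarray,
    window: int = 5,
    d_min_px: float = CLUB_MIN_DISPLACEMENT_PX,
) -> np.ndarray:
    """Theta per frame: angle of the club's motion relative to the tentacle axis.

    The club direction at frame i is the tip displacement over the
    centered window [i - w//2, i + w//2]; theta is the signed angle from
    the head-to-tip axis to that direction. NaN where the displacement is
    below ``d_min_px`` (club effectively stationary) or near the series
    edges.
    """
    if window < 3:
        raise ParameterError("club_angle window must be >= 3")
    head = np.asarray(head, dtype=float)
    tip = np.asarray(club_tip, dtype=float)
    n = len(tip)
    half = window // 2
    theta = np.full(n, np.nan)
    if n < window:
        return theta
    disp = np.full((n, 2), np.nan)
    disp[half : n - half] = tip[2 * half :] - tip[: n - 2 * half]
    axis = _yup(tip) - _yup(head)
    moving = np.linalg.norm(disp, axis=-1) >= d_min_px
    valid = moving & (np.linalg.norm(axis, axis=-1) > 0) & ~np.isnan(disp).any(axis=1)
    theta[valid] = _angle_or_nan(axis[valid], _yup(disp[valid]))
    return theta


def horizontal_speed(
    x_px: np.ndarray, fps: float, mm_per_px: float, window: int = 5
) -> np.ndarray:
    """Signed horizontal speed (mm/s) from an x-coordinate series.

    Central difference of the moving-average-smoothed x coordinate,
    scaled by fps and the pixel pitch. Positive is rightward (+x in the
    image). Needs at least three frames.
    """
    x_px = np.asarray(x_px, dtype=float)
    if len(x_px) < 3:
        raise InsufficientDataError("horizontal_speed needs >= 3 frames")
    xs = smooth(x_px, window)
    return np.gradient(xs) * fps * mm_per_px


def target_distance(
    head: np.ndarray, prey_ref: np.ndarray, mantle_scale_px: float
) -> float | np.ndarray:
    """Head-to-prey distance in mantle lengths (trial median mantle scale)."""
    if mantle_scale_px <= 0:
        raise DegenerateGeometryError("mantle scale must be > 0")
    head = np.asarray(head, dtype=float)
    prey_ref = np.asarray(prey_ref, dtype=float)
    d = np.linalg.norm(prey_ref - head, axis=-1) / mantle_scale_px
    return float(d) if d.ndim == 0 else d


@dataclass
class KinematicSeries:
    """Per-frame kinematic variables for one trial.

    ``frame`` columns: time_s, head_x_px, head_y_px, heading_x,
    heading_y (y-up), mantle_len_px, alpha_deg, beta_left_deg,
    beta_right_deg, delta_left_deg, delta_right_deg, theta_left_deg,
    theta_right_deg, ext_left_ml, ext_right_ml, cutt_x_mm, prey_x_mm,
    cutt_speed_mm_s, prey_speed_mm_s, target_dist_ml. Undefined angles
    are NaN. ``mantle_scale_px`` is the trial-level scale (median of the
    per-frame mantle length, robust to soft-body shape change).
    """

    metadata: TrialMetadata
    frame: pd.DataFrame
    mantle_scale_px: float

    @property
    def n_frames(self) -> int:
        return len(self.frame)

    @property
    def time_s(self) -> np.ndarray:
        return self.frame["time_s"].to_numpy()

    def __getattr__(self, name: str):
        if name.startswith("_"):
            raise AttributeError(name)
        try:
            return self.frame[name].to_numpy()
        except KeyError:
            raise AttributeError(name) from None

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index_label="frame", float_format="%.6f")
        return path


def prey_reference(clean: CleanTrack) -> np.ndarray:
    """Prey reference point per frame: midpoint of the shrimp eyes (image px).

    Strikes target the anterior body; the hook is a rig artifact.
    """
    return 0.5 * (clean.xy(BodyPart.SHRIMP_LEFT_EYE) + clean.xy(BodyPart.SHRIMP_RIGHT_EYE))


def compute_kinematics(
    clean: CleanTrack,
    speed_window: int | None = None,
    club_window: int = 5,
    extension_threshold_ml: float = EXTENSION_THRESHOLD_ML,
) -> KinematicSeries:
    """Run the full per-frame kinematic extraction on a cleaned track."""
    md = clean.metadata
    window = clean.smoothing_window if speed_window is None else speed_window
    n = clean.n_frames
    if n < 3:
        raise InsufficientDataError("kinematics needs >= 3 frames")

    head, heading, mantle_len = body_axis(
        clean.xy(BodyPart.LEFT_EYE), clean.xy(BodyPart.RIGHT_EYE), clean.xy(BodyPart.MANTLE_END)
    )
    mantle_scale = float(np.median(mantle_len))
    prey = prey_reference(clean)

    alpha = _angle_or_nan(heading, _yup(prey) - _yup(head))
    beta_l = _angle_or_nan(heading, _yup(clean.xy(BodyPart.LEFT_EYE)) - _yup(clean.xy(BodyPart.MANTLE_END)))
    beta_r = _angle_or_nan(heading, _yup(clean.xy(BodyPart.RIGHT_EYE)) - _yup(clean.xy(BodyPart.MANTLE_END)))

    out = {
        "time_s": np.arange(n) / md.fps,
        "head_x_px": head[:, 0],
        "head_y_px": head[:, 1],
        "heading_x": heading[:, 0],
        "heading_y": heading[:, 1],
        "mantle_len_px": mantle_len,
        "alpha_deg": alpha,
        "beta_left_deg": beta_l,
        "beta_right_deg": beta_r,
    }

    for side, part in (("left", BodyPart.LEFT_CLUB_TIP), ("right", BodyPart.RIGHT_CLUB_TIP)):
        tip = clean.xy(part)
        ext = np.linalg.norm(tip - head, axis=-1) / mantle_scale
        extended = ext > extension_threshold_ml
        delta = _angle_or_nan(heading, _yup(tip) - _yup(head))
        delta[~extended] = np.nan
        theta = club_angle(head, tip, window=club_window)
        theta[~extended] = np.nan
        out[f"delta_{side}_deg"] = delta
        out[f"theta_{side}_deg"] = theta
        out[f"ext_{side}_ml"] = ext

    out["cutt_x_mm"] = head[:, 0] * md.mm_per_px
    out["prey_x_mm"] = prey[:, 0] * md.mm_per_px
    out["cutt_speed_mm_s"] = horizontal_speed(head[:, 0], md.fps, md.mm_per_px, window)
    out["prey_speed_mm_s"] = horizontal_speed(prey[:, 0], md.fps, md.mm_per_px, window)
    out["target_dist_ml"] = target_distance(head, prey, mantle_scale)

    return KinematicSeries(
        metadata=md,
        frame=pd.DataFrame(out, index=pd.RangeIndex(n)),
        mantle_scale_px=mantle_scale,
    )
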