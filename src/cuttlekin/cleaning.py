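"""Likelihood gating and gap interpolation for raw pose tracks.

Markerless pose estimators occasionally mislabel occluded body parts;
the estimator's per-point confidence flags most of these. Cleaning
therefore (1) drops coordinates whose likelihood falls below a
threshold, (2) optionally drops single-frame jumps larger than a
displacement gate, and (3) fills the resulting gaps by linear
interpolation in frame index. Raw positions stay authoritative:
smoothing exists only as a helper for derivative estimation and is never
applied to stored coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cuttlekin.errors import ParameterError, UnrecoverablePartError
from cuttlekin.pose_io import ALL_PARTS, BodyPart, PoseTrack, TrialMetadata

DEFAULT_LIKELIHOOD_THRESHOLD = 0.9
DEFAULT_SMOOTHING_WINDOW = 5  # frames; ~56 ms at 90 fps


@dataclass
class CleanTrack:
    """Gap-free coordinates plus a per-frame, per-part interpolation mask.

    ``data`` has (bodypart, coord) columns with coord in {x, y};
    ``interpolated`` has one boolean column per body part, true exactly
    where the raw value was gated out or absent.
    """

    metadata: TrialMetadata
    data: pd.DataFrame
    interpolated: pd.DataFrame
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("CleanTrack must be gap-free")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ParameterError("smoothing_window must be odd and >= 1")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def xy(self, part: BodyPart) -> np.ndarray:
        return self.data[part.value][["x", "y"]].to_numpy(dtype=float)

    def x(self, part: BodyPart) -> np.ndarray:
        return self.data[(part.value, "x")].to_numpy(dtype=float)

    def y(self, part: BodyPart) -> np.ndarray:
        return self.data[(part.value, "y")].to_numpy(dtype=float)


def gate_by_likelihood(track: PoseTrack, threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD) -> PoseTrack:
    """Mark coordinates with likelihood below ``threshold`` as missing (NaN).

    ``threshold == 0`` is a vacuous gate; coordinates at or above the
    threshold are left bit-identical.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
    out = track.data.copy()
    for part in ALL_PARTS:
        low = out[(part.value, "likelihood")].to_numpy(dtype=float) < threshold
        out.loc[low, (part.value, "x")] = np.nan
        out.loc[low, (part.value, "y")] = np.nan
    return PoseTrack(metadata=track.metadata, data=out)


def gate_by_jump(track: PoseTrack, max_jump_px: float) -> PoseTrack:
    """Optional outlier gate: drop points displaced > ``max_jump_px`` from the
    previous retained point of the same part. Off by default in the pipeline;
    catches confident mislabels that likelihood gating misses."""
    if max_jump_px <= 0:
        raise ParameterError("max_jump_px must be > 0")
    out = track.data.copy()
    for part in ALL_PARTS:
        xy = out[part.value][["x", "y"]].to_numpy(dtype=float)
        drop = np.zeros(len(xy), dtype=bool)
        last = None
        for i in range(len(xy)):
            if np.isnan(xy[i]).any():
                continue
            if last is not None and np.hypot(*(xy[i] - last)) > max_jump_px:
                drop[i] = True
                continue
            last = xy[i]
        out.loc[drop, (part.value, "x")] = np.nan
        out.loc[drop, (part.value, "y")] = np.nan
    return PoseTrack(metadata=track.metadata, data=out)


def interpolate_gaps(
    track: PoseTrack, smoothing_window: int = DEFAULT_SMOOTHING_WINDOW
) -> CleanTrack:
    """Fill NaN gaps by linear interpolation in frame index.

    Interior gaps are interpolated independently for x and y; leading and
    trailing gaps are filled by constant extension of the nearest observed
    value (no extrapolated motion at recording boundaries). Exact for
    affine trajectories; idempotent on its own output.
    """
    parts = [p.value for p in ALL_PARTS]
    coords = {}
    mask = {}
    for part in parts:
        sub = track.data[part][["x", "y"]].astype(float)
        missing = sub.isna().any(axis=1)
        if missing.all():
            raise UnrecoverablePartError(f"body part {part!r} has no observed frame")
        # a frame missing either coordinate is treated as missing both
        sub = sub.mask(np.broadcast_to(missing.to_numpy()[:, None], sub.shape))
        filled = sub.interpolate(method="index", limit_direction="both", axis=0)
        coords[(part, "x")] = filled["x"].to_numpy()
        coords[(part, "y")] = filled["y"].to_numpy()
        mask[part] = missing.to_numpy()
    data = pd.DataFrame(coords, index=pd.RangeIndex(track.n_frames))
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["bodyparts", "coords"])
    interp = pd.DataFrame(mask, index=pd.RangeIndex(track.n_frames))
    return CleanTrack(
        metadata=track.metadata,
        data=data,
        interpolated=interp,
        smoothing_window=smoothing_window,
    )


def clean(
    track: PoseTrack,
    likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
    jump_gate_px: float | None = None,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
) -> CleanTrack:
    """Full cleaning pass: likelihood gate, optional jump gate, interpolate."""
    gated = gate_by_likelihood(track, likelihood_threshold)
    if jump_gate_px is not None:
        gated = gate_by_jump(gated, jump_gate_px)
    return interpolate_gaps(gated, smoothing_window=smoothing_window)


def smooth(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with the window shrinking symmetrically at edges.

    ``window == 1`` is the identity. Preserves affine signals in the
    interior and constants everywhere.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(series, dtype=float)
    n = len(x)
    if window > n:
        raise ParameterError(f"window {window} exceeds series length {n}")
    if window == 1:
        return x.copy()
    half = window // 2
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(n):
        h = min(half, i, n - 1 - i)  # symmetric shrink at the edges
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out
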