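"""Reading and writing pose tables in the DeepLabCut CSV dialect.

The dialect has three header rows (scorer, bodyparts, coords), one data
row per video frame, and x / y / likelihood columns for every tracked
body part. Coordinates are image coordinates: origin top-left, y
increasing downward, 0-based frame indices. All geometry downstream
converts to a y-up mathematical frame; this module stores what the file
stores.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from cuttlekin.errors import FormatError, IntegrityError, ParseError, ValidationError

COORDS = ("x", "y", "likelihood")


class BodyPart(str, Enum):
    """The nine tracked body parts: five on the cuttlefish, four on the shrimp."""

    # cuttlefish
    LEFT_EYE = "left_eye"
    RIGHT_EYE = "right_eye"
    LEFT_CLUB_TIP = "left_club_tip"
    RIGHT_CLUB_TIP = "right_club_tip"
    MANTLE_END = "mantle_end"
    # shrimp prey
    SHRIMP_LEFT_EYE = "shrimp_left_eye"
    SHRIMP_RIGHT_EYE = "shrimp_right_eye"
    SHRIMP_HOOK = "shrimp_hook"
    SHRIMP_TAIL = "shrimp_tail"

    @classmethod
    def cuttlefish(cls) -> tuple["BodyPart", ...]:
        return (cls.LEFT_EYE, cls.RIGHT_EYE, cls.LEFT_CLUB_TIP, cls.RIGHT_CLUB_TIP, cls.MANTLE_END)

    @classmethod
    def shrimp(cls) -> tuple["BodyPart", ...]:
        return (cls.SHRIMP_LEFT_EYE, cls.SHRIMP_RIGHT_EYE, cls.SHRIMP_HOOK, cls.SHRIMP_TAIL)


ALL_PARTS: tuple[BodyPart, ...] = BodyPart.cuttlefish() + BodyPart.shrimp()

#: Default mapping from file body-part names to canonical labels. Kept in
#: config (overridable per call) so retrained networks with different
#: label spellings can be read without code changes.
DEFAULT_LABEL_MAP: dict[str, BodyPart] = {p.value: p for p in ALL_PARTS}


class TrialMetadata(BaseModel):
    """Acquisition metadata for one trial.

    The rig records 2048 x 2048 px frames at 90 fps; sessions last 120 s.
    ``mm_per_px`` is a required calibration input: the recordings carry a
    scale bar but no stored pixel pitch, so it cannot be inferred.
    """

    animal_id: str
    trial_id: str
    fps: float = 90.0
    mm_per_px: float = 0.5
    frame_size: tuple[int, int] = (2048, 2048)
    session_length_s: float = 120.0

    @model_validator(mode="after")
    def _check_positive(self) -> "TrialMetadata":
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be > 0")
        if self.session_length_s <= 0:
            raise ValueError("session_length_s must be > 0")
        return self

    @property
    def max_frames(self) -> int:
        return int(round(self.fps * self.session_length_s)) + 1


@dataclass
class PoseTrack:
    """Raw per-frame image coordinates with confidence for all nine body parts.

    ``data`` has a two-level column index ``(bodypart, coord)`` with
    coord in {x, y, likelihood} and one row per frame (RangeIndex from 0).
    Gaps (after likelihood gating) are NaN in x/y.
    """

    metadata: TrialMetadata
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        cols = self.data.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise ValidationError("pose data needs (bodypart, coord) columns")
        parts = set(cols.get_level_values(0))
        missing = [p.value for p in ALL_PARTS if p.value not in parts]
        if missing:
            raise FormatError(f"missing body parts: {', '.join(missing)}")
        if len(self.data) and not (self.data.index == np.arange(len(self.data))).all():
            raise ValidationError("frame indices must be 0..N-1, strictly increasing")
        lik = self.data.loc[:, (slice(None), "likelihood")].to_numpy(dtype=float)
        finite = lik[np.isfinite(lik)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValidationError("likelihood outside [0, 1]")
        if len(self.data) > self.metadata.max_frames:
            raise ValidationError(
                f"{len(self.data)} frames exceeds fps x session_length + 1 "
                f"= {self.metadata.max_frames}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def part(self, part: BodyPart) -> pd.DataFrame:
        """The (x, y, likelihood) frame series of one body part."""
        return self.data[part.value]

    def xy(self, part: BodyPart) -> np.ndarray:
        """(N, 2) float array of image coordinates for one body part."""
        return self.data[part.value][["x", "y"]].to_numpy(dtype=float)

    def likelihood(self, part: BodyPart) -> np.ndarray:
        return self.data[(part.value, "likelihood")].to_numpy(dtype=float)

    def copy(self) -> "PoseTrack":
        return PoseTrack(metadata=self.metadata.model_copy(), data=self.data.copy())


def make_pose_frame(n_frames: int, scorer: str = "cuttlekin") -> pd.DataFrame:
    """An all-NaN pose DataFrame with the canonical column layout."""
    cols = pd.MultiIndex.from_product(
        [[p.value for p in ALL_PARTS], COORDS], names=["bodyparts", "coords"]
    )
    return pd.DataFrame(np.nan, index=pd.RangeIndex(n_frames), columns=cols)


def read_dlc_csv(
    path: str | Path,
    metadata: TrialMetadata,
    label_map: dict[str, BodyPart] | None = None,
) -> PoseTrack:
    """Read a DeepLabCut-dialect CSV into a :class:`PoseTrack`.

    Parameters
    ----------
    path
        CSV with three header rows (scorer / bodyparts / coords) and the
        frame index in the first column.
    metadata
        Trial metadata; the file itself carries no calibration.
    label_map
        File body-part name -> canonical label. Defaults to the identity
        mapping on the canonical names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    try:
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    file_parts = list(dict.fromkeys(raw.columns.get_level_values(1)))
    mapped: dict[BodyPart, str] = {}
    for name in file_parts:
        if name in label_map:
            mapped[label_map[name]] = name
    missing = [p.value for p in ALL_PARTS if p not in mapped]
    if missing:
        raise FormatError(f"{path}: header lacks body part(s): {', '.join(missing)}")

    out = make_pose_frame(len(raw))
    scorer = raw.columns.get_level_values(0)[0]
    for part, file_name in mapped.items():
        for coord in COORDS:
            col = raw[(scorer, file_name, coord)]
            values = pd.to_numeric(col, errors="coerce")
            bad = values.isna() & col.notna() & (col.astype(str).str.strip() != "")
            if bad.any():
                row = int(bad.idxmax())
                raise ParseError(
                    f"{path}: non-numeric value {col[row]!r} at frame {row}, "
                    f"column ({file_name}, {coord})"
                )
            out[(part.value, coord)] = values.to_numpy(dtype=float)
    out.index = pd.RangeIndex(len(out))
    return PoseTrack(metadata=metadata, data=out)


def write_dlc_csv(track: PoseTrack, path: str | Path, scorer: str = "cuttlekin") -> Path:
    """Write a :class:`PoseTrack` in the three-header-row dialect.

    Floats are written with six decimals so identical tracks produce
    byte-identical files; ``read_dlc_csv(write_dlc_csv(t))`` recovers the
    coordinates to within 1e-6 px.
    """
    path = Path(path)
    df = track.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, part, coord) for part, coord in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    df.index.name = None
    df.to_csv(path, float_format="%.6f")
    return path


@dataclass
class Table1Fixture:
    """Per-episode transcription of the study's summary table.

    One row per attention episode: animal, trial, whether the trial
    contained a tentacular strike attempt / success, the episode duration
    in seconds, and whether the episode immediately preceded a strike.
    """

    episodes: pd.DataFrame = field(repr=False)

    EXPECTED = dict(animals=10, trials=16, episodes=29, pre_strike=10)

    def __post_init__(self) -> None:
        df = self.episodes
        counts = dict(
            animals=df["animal"].nunique(),
            trials=len(df.groupby(["animal", "trial"])),
            episodes=len(df),
            pre_strike=int(df["pre_strike"].sum()),
        )
        if counts != self.EXPECTED:
            raise IntegrityError(f"fixture counts {counts} != expected {self.EXPECTED}")

    @property
    def n_animals(self) -> int:
        return self.episodes["animal"].nunique()

    @property
    def n_trials(self) -> int:
        return len(self.episodes.groupby(["animal", "trial"]))

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    def trials(self) -> pd.DataFrame:
        """One row per trial with attempt/success flags."""
        return (
            self.episodes.groupby(["animal", "trial"])[["attempt", "success"]]
            .any()
            .reset_index()
        )


def load_table1(path: str | Path | None = None) -> Table1Fixture:
    """Load the packaged per-episode summary table (or a compatible CSV)."""
    if path is None:
        ref = importlib.resources.files("cuttlekin.data").joinpath("table1.csv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"animal", "trial", "attempt", "success", "duration_s", "pre_strike"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"episode table lacks columns: {sorted(missing)}")
    for col in ("attempt", "success", "pre_strike"):
        df[col] = df[col].astype(bool)
    return Table1Fixture(episodes=df)
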