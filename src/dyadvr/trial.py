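"""Domain types and I/O for two-agent arena trials.

A trial is a pair of frame-aligned trajectories, one per fish, sampled at a
fixed frame interval (100 ms by default). Trial logs are long-form CSV with
one row per (frame, fish): columns ``frame,fish_id,x,y,heading,speed,turn``.
Coordinates have their origin at the arena center (units = VR units, y up);
headings are degrees counterclockwise from +x, normalized to (-180, +180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .angles import wrap_angle
from .config import ArenaProtocolConfig

TRIAL_COLUMNS = ["frame", "fish_id", "x", "y", "heading", "speed", "turn"]


class TrialFormatError(ValueError):
    """The log file does not have the expected tabular layout."""


class TrialAlignmentError(ValueError):
    """The two fish do not share an identical frame set."""


class TrialValidationError(ValueError):
    """Values in the log violate basic trial invariants."""


class Condition(str, Enum):
    NO_SHOCK = "no_shock"
    SHOCK = "shock"


class GenotypePair(str, Enum):
    WT_WT = "WT_WT"
    WT_TG = "WT_TG"


@dataclass(frozen=True)
class FishFrame:
    """One fish at one frame: position, heading and kinematics."""

    t: int
    x: float
    y: float
    heading: float  # degrees in (-180, +180]
    speed: float    # VR units / s, nonnegative
    turn: float     # degrees / s, signed

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y])


class Trajectory:
    """Column-array view of one fish's frames within a trial."""

    __slots__ = ("t", "x", "y", "heading", "speed", "turn")

    def __init__(self, t, x, y, heading, speed, turn):
        self.t = np.asarray(t, dtype=np.int64)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.heading = np.asarray(heading, dtype=float)
        self.speed = np.asarray(speed, dtype=float)
        self.turn = np.asarray(turn, dtype=float)
        n = len(self.t)
        for name in self.__slots__:
            if len(getattr(self, name)) != n:
                raise TrialValidationError("trajectory columns must share one length")

    def __len__(self) -> int:
        return len(self.t)

    def frame(self, i: int) -> FishFrame:
        return FishFrame(
            t=int(self.t[i]),
            x=float(self.x[i]),
            y=float(self.y[i]),
            heading=float(self.heading[i]),
            speed=float(self.speed[i]),
            turn=float(self.turn[i]),
        )

    def frames(self) -> list[FishFrame]:
        return [self.frame(i) for i in range(len(self))]

    @classmethod
    def from_frames(cls, frames: Sequence[FishFrame]) -> "Trajectory":
        return cls(
            t=[f.t for f in frames],
            x=[f.x for f in frames],
            y=[f.y for f in frames],
            heading=[f.heading for f in frames],
            speed=[f.speed for f in frames],
            turn=[f.turn for f in frames],
        )

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class DyadTrial:
    """Two frame-aligned trajectories plus trial metadata."""

    fish_a: Trajectory
    fish_b: Trajectory
    pair_id: str = "pair0"
    condition: Condition = Condition.NO_SHOCK
    genotype_pair: GenotypePair = GenotypePair.WT_WT
    frame_interval_ms: float = 100.0
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self) -> None:
        if len(self.fish_a) == 0:
            raise TrialValidationError("trial must contain at least one frame")
        if len(self.fish_a) != len(self.fish_b) or not np.array_equal(
            self.fish_a.t, self.fish_b.t
        ):
            raise TrialAlignmentError("fish_a and fish_b must share identical frames")
        self.condition = Condition(self.condition)
        self.genotype_pair = GenotypePair(self.genotype_pair)

    @property
    def n_frames(self) -> int:
        return len(self.fish_a)

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_ms / 1000.0

    def trajectory(self, fish: str) -> Trajectory:
        if fish == self.id_a:
            return self.fish_a
        if fish == self.id_b:
            return self.fish_b
        raise KeyError(f"unknown fish id {fish!r}")

    def opponent(self, fish: str) -> str:
        if fish == self.id_a:
            return self.id_b
        if fish == self.id_b:
            return self.id_a
        raise KeyError(f"unknown fish id {fish!r}")


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``validate_trial`` reports, never raises."""

    fish: str
    frame: int
    kind: str
    message: str


def read_trial(
    path: str | Path,
    config: ArenaProtocolConfig | None = None,
    pair_id: str | None = None,
    condition: str = "no_shock",
    genotype_pair: str = "WT_WT",
) -> DyadTrial:
    """Read a long-form trial CSV into a frame-aligned :class:`DyadTrial`.

    Rows are sorted by frame; headings are normalized to (-180, +180].
    The two fish ids are assigned to fish_a / fish_b in sorted order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TrialFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path} is missing columns {missing}")
    ids = sorted(df["fish_id"].astype(str).unique())
    if len(ids) != 2:
        raise TrialFormatError(f"{path} must contain exactly two fish ids, got {ids}")
    numeric = df[["x", "y", "heading", "speed", "turn"]].to_numpy(dtype=float)
    if not np.isfinite(numeric).all():
        raise TrialValidationError(f"{path} contains non-finite values")
    parts = {}
    for fid in ids:
        sub = df[df["fish_id"].astype(str) == fid].sort_values("frame")
        parts[fid] = Trajectory(
            t=sub["frame"].to_numpy(),
            x=sub["x"].to_numpy(float),
            y=sub["y"].to_numpy(float),
            heading=wrap_angle(sub["heading"].to_numpy(float)),
            speed=sub["speed"].to_numpy(float),
            turn=sub["turn"].to_numpy(float),
        )
    a, b = parts[ids[0]], parts[ids[1]]
    if len(a) != len(b) or not np.array_equal(a.t, b.t):
        raise TrialAlignmentError(f"{path}: fish {ids[0]} and {ids[1]} frame sets differ")
    interval = config.frame_interval_ms if config is not None else 100.0
    return DyadTrial(
        fish_a=a,
        fish_b=b,
        pair_id=pair_id if pair_id is not None else path.stem,
        condition=condition,
        genotype_pair=genotype_pair,
        frame_interval_ms=interval,
        id_a=ids[0],
        id_b=ids[1],
    )


def trial_to_frame_table(trial: DyadTrial) -> pd.DataFrame:
    """Long-form DataFrame of a trial (one row per frame per fish)."""
    rows = []
    for fid, traj in ((trial.id_a, trial.fish_a), (trial.id_b, trial.fish_b)):
        rows.append(
            pd.DataFrame(
                {
                    "frame": traj.t,
                    "fish_id": fid,
                    "x": traj.x,
                    "y": traj.y,
                    "heading": traj.heading,
                    "speed": traj.speed,
                    "turn": traj.turn,
                }
            )
        )
    return pd.concat(rows, ignore_index=True).sort_values(
        ["frame", "fish_id"], kind="stable"
    )[TRIAL_COLUMNS]


def write_trial(trial: DyadTrial, path: str | Path) -> None:
    """Write a trial as CSV with 6-decimal fixed precision.

    A file written here reads back identically (at the written precision)
    through :func:`read_trial`.
    """
    df = trial_to_frame_table(trial)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")


def validate_trial(
    trial: DyadTrial, config: ArenaProtocolConfig
) -> list[Violation]:
    """Report invariant violations; total (never raises on bad values)."""
    violations: list[Violation] = []
    for fid, traj in ((trial.id_a, trial.fish_a), (trial.id_b, trial.fish_b)):
        finite = np.isfinite(
            np.column_stack([traj.x, traj.y, traj.heading, traj.speed, traj.turn])
        ).all(axis=1)
        for i in np.flatnonzero(~finite):
            violations.append(
                Violation(fid, int(traj.t[i]), "non_finite", "non-finite value")
            )
        r2 = traj.x**2 + traj.y**2
        outside = finite & (r2 > config.arena_radius**2 * (1 + 1e-12))
        for i in np.flatnonzero(outside):
            violations.append(
                Violation(
                    fid,
                    int(traj.t[i]),
                    "out_of_arena",
                    f"|pos|={np.sqrt(r2[i]):.3f} > arena radius {config.arena_radius}",
                )
            )
        bad_heading = finite & ~(
            (traj.heading > -180.0) & (traj.heading <= 180.0)
        )
        for i in np.flatnonzero(bad_heading):
            violations.append(
                Violation(
                    fid, int(traj.t[i]), "heading_range", "heading outside (-180, 180]"
                )
            )
        bad_speed = finite & (traj.speed < 0)
        for i in np.flatnonzero(bad_speed):
            violations.append(
                Violation(fid, int(traj.t[i]), "negative_speed", "speed < 0")
            )
    return violations
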