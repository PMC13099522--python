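"""Per-frame geometric classifiers for dyadic arena trials.

Relative bearing is the signed angle from the observer's heading to the
observer-to-target vector, with negative values on the observer's LEFT
(so the left monocular range [-135, -30) holds negative bearings).

Attack posture: the forward ray from the observer's mouth (avatar_length/2
ahead of the logged body center) passes through the disk of radius
``attack_circle_radius`` centered on the opponent.

Bite: the biter's mouth point lies within ``midbody_halfwidth`` of the
opponent's mid-body segment (central ``midbody_fraction`` of the body
axis) while the biter's heading is within ±``bite_angle_halfwidth`` of the
line perpendicular to the opponent's body axis; events are counted on the
rising edge only (a collision lasting several frames is one bite).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .angles import wrap_angle, heading_unit
from .config import ArenaProtocolConfig
from .trial import DyadTrial, FishFrame, Trajectory


class DegenerateGeometryError(ValueError):
    """Observer and target coincide; bearing is undefined."""


class ViewLabel(IntEnum):
    LEFT = 0
    BINOCULAR = 1
    RIGHT = 2
    BLIND = 3


@dataclass(frozen=True)
class BiteEvent:
    """Rising-edge mouth-to-mid-body collision event."""

    t: int
    biter: str
    bitten: str

    def __post_init__(self) -> None:
        if self.biter == self.bitten:
            raise ValueError("biter and bitten must differ")


def relative_bearing(observer: FishFrame, target_pos) -> float:
    """Signed bearing (degrees) from observer heading to target; left < 0."""
    tx, ty = float(target_pos[0]), float(target_pos[1])
    dx, dy = tx - observer.x, ty - observer.y
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("observer and target positions coincide")
    angle_to_target = np.degrees(np.arctan2(dy, dx))
    return wrap_angle(observer.heading - angle_to_target)


def bearing_series(observer: Trajectory, target: Trajectory) -> np.ndarray:
    """Per-frame bearing of the target in the observer's frame.

    Coincident-position frames yield NaN (classified as blind).
    """
    dx = target.x - observer.x
    dy = target.y - observer.y
    with np.errstate(invalid="ignore"):
        angle = np.degrees(np.arctan2(dy, dx))
    bearings = wrap_angle(observer.heading - angle)
    bearings = np.where((dx == 0) & (dy == 0), np.nan, bearings)
    return bearings


def classify_view(bearing: float, config: ArenaProtocolConfig) -> ViewLabel:
    """Map one bearing to its eye-field label (total partition)."""
    lab = classify_views(np.array([bearing]), config)[0]
    return ViewLabel(int(lab))


def classify_views(bearings: np.ndarray, config: ArenaProtocolConfig) -> np.ndarray:
    """Vectorized view classification; NaN bearings map to BLIND.

    Boundary convention: LEFT is [lo, hi), BINOCULAR is closed, RIGHT is
    (lo, hi], so each boundary bearing has exactly one label.
    """
    b = np.asarray(bearings, dtype=float)
    le, bi, ri = config.left_eye_range, config.binocular_range, config.right_eye_range
    labels = np.full(b.shape, ViewLabel.BLIND, dtype=np.int64)
    labels[(b >= le[0]) & (b < le[1])] = ViewLabel.LEFT
    labels[(b >= bi[0]) & (b <= bi[1])] = ViewLabel.BINOCULAR
    labels[(b > ri[0]) & (b <= ri[1])] = ViewLabel.RIGHT
    labels[np.isnan(b)] = ViewLabel.BLIND
    return labels


def _mouth_points(traj: Trajectory, config: ArenaProtocolConfig):
    ux, uy = heading_unit(traj.heading)
    half = config.avatar_length / 2.0
    return traj.x + half * ux, traj.y + half * uy


def is_attack_posture(
    observer: FishFrame, target: FishFrame, config: ArenaProtocolConfig
) -> bool:
    """True iff the forward ray from the observer's mouth hits the
    25-unit disk centered at the target's position."""
    if observer.x == target.x and observer.y == target.y:
        raise DegenerateGeometryError("observer and target positions coincide")
    obs = Trajectory([observer.t], [observer.x], [observer.y],
                     [observer.heading], [observer.speed], [observer.turn])
    tgt = Trajectory([target.t], [target.x], [target.y],
                     [target.heading], [target.speed], [target.turn])
    return bool(attack_posture_mask(obs, tgt, config)[0])


def attack_posture_mask(
    observer: Trajectory, target: Trajectory, config: ArenaProtocolConfig
) -> np.ndarray:
    """Per-frame attack-posture booleans (ray-disk intersection)."""
    mx, my = _mouth_points(observer, config)
    ux, uy = heading_unit(observer.heading)
    wx = target.x - mx
    wy = target.y - my
    r = config.attack_circle_radius
    dist2 = wx * wx + wy * wy
    proj = wx * ux + wy * uy
    perp2 = dist2 - proj * proj
    inside = dist2 <= r * r
    ahead = (proj > 0) & (perp2 <= r * r)
    return inside | ahead


def attack_posture_rate(
    trial: DyadTrial, fish: str, config: ArenaProtocolConfig
) -> float:
    """Percentage of frames in which ``fish`` holds an attack posture."""
    obs = trial.trajectory(fish)
    tgt = trial.trajectory(trial.opponent(fish))
    mask = attack_posture_mask(obs, tgt, config)
    return 100.0 * float(np.count_nonzero(mask)) / len(obs)


def _bite_candidate_mask(
    biter: Trajectory, opponent: Trajectory, config: ArenaProtocolConfig
) -> np.ndarray:
    mx, my = _mouth_points(biter, config)
    # opponent body axis: segment of avatar_length centered on its position
    vx, vy = heading_unit(opponent.heading)
    half_mid = config.avatar_length * config.midbody_fraction / 2.0
    wx = mx - opponent.x
    wy = my - opponent.y
    s = np.clip(wx * vx + wy * vy, -half_mid, half_mid)
    cx = wx - s * vx
    cy = wy - s * vy
    touching = cx * cx + cy * cy <= config.midbody_halfwidth**2
    # inclination w.r.t. the perpendicular of the opponent's body axis
    ux, uy = heading_unit(biter.heading)
    cos_axis = np.abs(ux * vx + uy * vy)
    angle_to_axis = np.degrees(np.arccos(np.clip(cos_axis, 0.0, 1.0)))
    inclination_ok = (90.0 - angle_to_axis) <= config.bite_angle_halfwidth
    return touching & inclination_ok


def detect_bites(trial: DyadTrial, config: ArenaProtocolConfig) -> list[BiteEvent]:
    """Rising-edge bite events for both directions, sorted by frame."""
    events: list[BiteEvent] = []
    pairs = (
        (trial.id_a, trial.fish_a, trial.id_b, trial.fish_b),
        (trial.id_b, trial.fish_b, trial.id_a, trial.fish_a),
    )
    for biter_id, biter, bitten_id, bitten in pairs:
        cand = _bite_candidate_mask(biter, bitten, config)
        rising = cand & ~np.concatenate([[False], cand[:-1]])
        for i in np.flatnonzero(rising):
            events.append(BiteEvent(t=int(trial.fish_a.t[i]), biter=biter_id,
                                    bitten=bitten_id))
    events.sort(key=lambda e: (e.t, e.biter))
    return events


def near_rate(trial: DyadTrial, config: ArenaProtocolConfig) -> float:
    """Percentage of frames with inter-fish distance <= near_threshold."""
    d = np.hypot(trial.fish_a.x - trial.fish_b.x, trial.fish_a.y - trial.fish_b.y)
    return 100.0 * float(np.count_nonzero(d <= config.near_threshold)) / len(d)


def center_occupancy_rate(
    trial: DyadTrial, fish: str, config: ArenaProtocolConfig
) -> float:
    """Percentage of frames the fish spends strictly inside the inner circle."""
    traj = trial.trajectory(fish)
    r2 = traj.x**2 + traj.y**2
    return 100.0 * float(np.count_nonzero(r2 < config.inner_radius**2)) / len(traj)


def view_label_table(trial: DyadTrial, config: ArenaProtocolConfig):
    """Per-frame label track for both fish as a DataFrame.

    Columns: frame, fish_id, bearing_deg, view_label, attack_posture,
    near, in_center.
    """
    import pandas as pd

    d = np.hypot(trial.fish_a.x - trial.fish_b.x, trial.fish_a.y - trial.fish_b.y)
    frames = []
    for fid in (trial.id_a, trial.id_b):
        obs = trial.trajectory(fid)
        tgt = trial.trajectory(trial.opponent(fid))
        bearings = bearing_series(obs, tgt)
        labels = classify_views(bearings, config)
        frames.append(
            pd.DataFrame(
                {
                    "frame": obs.t,
                    "fish_id": fid,
                    "bearing_deg": bearings,
                    "view_label": [ViewLabel(v).name for v in labels],
                    "attack_posture": attack_posture_mask(obs, tgt, config),
                    "near": d <= config.near_threshold,
                    "in_center": obs.x**2 + obs.y**2 < config.inner_radius**2,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
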