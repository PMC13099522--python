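"""Arena geometry and stimulation-protocol constants.

The virtual arena is a circle of radius 100 VR units with the two fish
avatars (25 units long) starting 100 units apart at (50, 0) and (-50, 0).
The horizontal visual field is split into a left monocular range
[-135, -30), a frontal binocular range [-30, +30] and a right monocular
range (+30, +135]; bearings outside those ranges are the blind spot.
Negative bearings are on the observer's left.

The shock protocol delivers a 0.5 V mild pulse for 300 ms at the start of
every 1 s cycle to both fish; a bite triggers a 100 ms 4 V transient to the
bitten fish and relieves the biter of the mild stimulus for 2 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class ArenaProtocolConfig:
    """All geometric and stimulus constants of the dyadic VR task.

    Lengths are in VR units, durations in the unit given by the field
    suffix, angles in degrees. ``midbody_fraction`` and
    ``midbody_halfwidth`` describe the 2D collision proxy for the avatar's
    mid-body section: the central fraction of the body axis, padded
    laterally by the half-width.
    """

    arena_radius: float = 100.0
    inner_radius: float = 70.0
    avatar_length: float = 25.0
    near_threshold: float = 50.0
    left_eye_range: tuple[float, float] = (-135.0, -30.0)   # [lo, hi)
    binocular_range: tuple[float, float] = (-30.0, 30.0)    # [lo, hi]
    right_eye_range: tuple[float, float] = (30.0, 135.0)    # (lo, hi]
    toward_range_halfwidth: float = 90.0
    bite_angle_halfwidth: float = 75.0
    attack_circle_radius: float = 25.0
    midbody_fraction: float = 1.0 / 3.0
    midbody_halfwidth: float = 2.0
    mild_voltage: float = 0.5
    mild_on_ms: float = 300.0
    mild_period_ms: float = 1000.0
    transient_voltage: float = 4.0
    transient_ms: float = 100.0
    relief_s: float = 120.0
    frame_interval_ms: float = 100.0
    start_positions: tuple[tuple[float, float], tuple[float, float]] = (
        (50.0, 0.0),
        (-50.0, 0.0),
    )
    high_proximity_threshold: float = 20.0
    low_proximity_threshold: float = 100.0
    fbv_bin_width: float = 10.0
    fbv_n_bins: int = 20
    # minimum approach-episode length in frames (single-frame artifacts are
    # not meaningful at 100 ms sampling)
    min_approach_frames: int = 3

    def __post_init__(self) -> None:
        positive = {
            "arena_radius": self.arena_radius,
            "inner_radius": self.inner_radius,
            "avatar_length": self.avatar_length,
            "near_threshold": self.near_threshold,
            "attack_circle_radius": self.attack_circle_radius,
            "midbody_fraction": self.midbody_fraction,
            "midbody_halfwidth": self.midbody_halfwidth,
            "mild_on_ms": self.mild_on_ms,
            "mild_period_ms": self.mild_period_ms,
            "transient_ms": self.transient_ms,
            "relief_s": self.relief_s,
            "frame_interval_ms": self.frame_interval_ms,
            "fbv_bin_width": self.fbv_bin_width,
            "fbv_n_bins": self.fbv_n_bins,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not self.inner_radius < self.arena_radius:
            raise ValueError("inner_radius must be smaller than arena_radius")
        le, bi, ri = self.left_eye_range, self.binocular_range, self.right_eye_range
        for lo, hi in (le, bi, ri):
            if not lo < hi:
                raise ValueError("eye ranges must have lo < hi")
        if not (le[1] == bi[0] and bi[1] == ri[0]):
            raise ValueError("eye ranges must be contiguous (left|binocular|right)")
        if le[0] != -ri[1]:
            raise ValueError("visual field must be symmetric about the midline")
        (ax, ay), (bx, by) = self.start_positions
        for x, y in self.start_positions:
            if x * x + y * y > self.arena_radius**2:
                raise ValueError("start positions must lie inside the arena")
        if (ax, ay) != (-bx, -by):
            raise ValueError("start positions must be symmetric about the origin")

    @property
    def relief_ms(self) -> float:
        return self.relief_s * 1000.0

    @property
    def view_field_span_deg(self) -> float:
        """Total covered (non-blind) visual field in degrees."""
        return self.right_eye_range[1] - self.left_eye_range[0]

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["start_positions"] = [list(p) for p in self.start_positions]
        for key in ("left_eye_range", "binocular_range", "right_eye_range"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ArenaProtocolConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "ArenaProtocolConfig":
        kwargs = dict(data)
        if "start_positions" in kwargs:
            kwargs["start_positions"] = tuple(
                tuple(float(v) for v in p) for p in kwargs["start_positions"]
            )
        for key in ("left_eye_range", "binocular_range", "right_eye_range"):
            if key in kwargs:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)
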