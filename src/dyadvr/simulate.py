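"""Synthetic dyad generator with controllable statistical structure.

Two kinematic point-agents (position + heading) move in the circular arena
at the study's frame rate (10 Hz, 18000 frames per 30-min trial). Three
knobs inject the structure each analysis stage is designed to recover:

* ``attraction_gain`` — each agent's heading relaxes toward the bearing of
  the opponent (offset by ``lateral_bias``); raises the attraction
  statistic and lowers mean mutual distance.
* ``coupling_gain`` — agent B's forward speed tracks A's speed of the
  previous frame; creates a recoverable A-to-B transfer-entropy flow.
* ``lateral_bias`` (degrees) — preferred bearing offset; positive keeps the
  opponent on the agent's LEFT, driving the left-eye index positive.

All randomness comes from one seeded ``numpy.random.Generator``
(PCG64), so trials are bit-reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .angles import wrap_angle
from .config import ArenaProtocolConfig
from .te import SymbolSeries
from .trial import DyadTrial, Trajectory


@dataclass(frozen=True)
class SimParams:
    """Generator knobs; defaults give two independent wandering agents."""

    n_frames: int = 18000
    seed: int = 0
    attraction_gain: float = 0.0     # per-frame heading relaxation in [0, 1]
    coupling_gain: float = 0.0       # follower speed coupling in [0, 1]
    lateral_bias: float = 0.0        # degrees; > 0 keeps opponent on the left
    base_speed: float = 30.0         # VR units / s
    speed_noise_sd: float = 10.0     # VR units / s
    heading_noise_sd: float = 15.0   # degrees / frame
    wall_mode: str = "steer_away"    # or "reflect"

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if self.speed_noise_sd < 0 or self.heading_noise_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        if not 0 <= self.coupling_gain <= 1:
            raise ValueError("coupling_gain must lie in [0, 1]")
        if self.attraction_gain < 0:
            raise ValueError("attraction_gain must be nonnegative")
        if self.wall_mode not in ("steer_away", "reflect"):
            raise ValueError("wall_mode must be 'steer_away' or 'reflect'")


def generate_dyad(
    params: SimParams,
    config: ArenaProtocolConfig | None = None,
    pair_id: str = "sim",
    condition: str = "no_shock",
) -> DyadTrial:
    """Simulate one dyad trial; deterministic given ``params.seed``."""
    if config is None:
        config = ArenaProtocolConfig()
    n = params.n_frames
    dt = config.frame_interval_ms / 1000.0
    rng = np.random.default_rng(params.seed)
    heading_noise = rng.normal(0.0, params.heading_noise_sd, size=(n, 2))
    speed_noise = rng.normal(0.0, params.speed_noise_sd, size=(n, 2))
    wall_noise = rng.normal(0.0, 10.0, size=(n, 2))

    x = np.empty((n, 2))
    y = np.empty((n, 2))
    heading = np.empty((n, 2))
    speed = np.empty((n, 2))
    (x[0, 0], y[0, 0]), (x[0, 1], y[0, 1]) = config.start_positions
    heading[0] = (90.0, 90.0)  # positioned in parallel, facing +y
    speed[0] = (params.base_speed, params.base_speed)
    r_max = config.arena_radius * 0.999

    for t in range(1, n):
        for i in (0, 1):
            j = 1 - i
            dx = x[t - 1, j] - x[t - 1, i]
            dy = y[t - 1, j] - y[t - 1, i]
            if dx == 0.0 and dy == 0.0:
                bearing = 0.0
            else:
                bearing = wrap_angle(
                    heading[t - 1, i] - math.degrees(math.atan2(dy, dx))
                )
            turn = -params.attraction_gain * wrap_angle(bearing + params.lateral_bias)
            heading[t, i] = wrap_angle(
                heading[t - 1, i] + turn + heading_noise[t, i]
            )
        autonomous = np.maximum(params.base_speed + speed_noise[t], 0.0)
        speed[t, 0] = autonomous[0]
        speed[t, 1] = (
            params.coupling_gain * speed[t - 1, 0]
            + (1.0 - params.coupling_gain) * autonomous[1]
        )
        for i in (0, 1):
            hx = math.cos(math.radians(heading[t, i]))
            hy = math.sin(math.radians(heading[t, i]))
            nx = x[t - 1, i] + speed[t, i] * dt * hx
            ny = y[t - 1, i] + speed[t, i] * dt * hy
            if nx * nx + ny * ny > config.arena_radius**2:
                if params.wall_mode == "steer_away":
                    # head back toward the arena center, with jitter
                    heading[t, i] = wrap_angle(
                        math.degrees(math.atan2(-y[t - 1, i], -x[t - 1, i]))
                        + wall_noise[t, i]
                    )
                else:  # reflect velocity across the wall tangent
                    rx, ry = x[t - 1, i], y[t - 1, i]
                    rnorm = math.hypot(rx, ry)
                    if rnorm > 0:
                        nxu, nyu = rx / rnorm, ry / rnorm
                        dot = hx * nxu + hy * nyu
                        rxv = hx - 2 * dot * nxu
                        ryv = hy - 2 * dot * nyu
                        heading[t, i] = wrap_angle(math.degrees(math.atan2(ryv, rxv)))
                hx = math.cos(math.radians(heading[t, i]))
                hy = math.sin(math.radians(heading[t, i]))
                nx = x[t - 1, i] + speed[t, i] * dt * hx
                ny = y[t - 1, i] + speed[t, i] * dt * hy
                rn = math.hypot(nx, ny)
                if rn > r_max:
                    nx *= r_max / rn
                    ny *= r_max / rn
            x[t, i], y[t, i] = nx, ny

    turn_series = np.vstack(
        [np.zeros((1, 2)), wrap_angle(np.diff(heading, axis=0)) / dt]
    )
    t_idx = np.arange(n)
    traj = [
        Trajectory(
            t=t_idx,
            x=x[:, i],
            y=y[:, i],
            heading=heading[:, i],
            speed=speed[:, i],
            turn=turn_series[:, i],
        )
        for i in (0, 1)
    ]
    return DyadTrial(
        fish_a=traj[0],
        fish_b=traj[1],
        pair_id=pair_id,
        condition=condition,
        frame_interval_ms=config.frame_interval_ms,
    )


def generate_scripted_approach(
    start_distance: float,
    stop_distance: float,
    approach_bearing_profile,
    config: ArenaProtocolConfig | None = None,
    n_frames: int = 60,
    pair_id: str = "scripted",
) -> DyadTrial:
    """One agent homing in on a static target along a bearing profile.

    ``approach_bearing_profile`` is either a sequence of bearings (degrees,
    one per frame; its length overrides ``n_frames``) or a callable mapping
    progress in [0, 1] to a bearing. Bearings must stay within the ±90°
    "moving toward" range so exactly one approach episode is detectable.
    The target sits at the origin heading +y; the approacher closes in
    along the +x axis from ``start_distance`` to ``stop_distance``.
    """
    if config is None:
        config = ArenaProtocolConfig()
    if not stop_distance < start_distance:
        raise ValueError("stop_distance must be smaller than start_distance")
    if stop_distance < 0:
        raise ValueError("stop_distance must be nonnegative")
    if callable(approach_bearing_profile):
        bearings = np.array(
            [approach_bearing_profile(k / (n_frames - 1)) for k in range(n_frames)]
        )
    else:
        bearings = np.asarray(approach_bearing_profile, dtype=float)
        n_frames = len(bearings)
    if n_frames < config.min_approach_frames:
        raise ValueError("profile too short to form an approach episode")
    if np.any(np.abs(bearings) > config.toward_range_halfwidth):
        raise ValueError(
            "infeasible profile: bearings must stay within the toward range"
        )
    dt = config.frame_interval_ms / 1000.0
    dists = np.linspace(start_distance, stop_distance, n_frames)
    ax = dists
    ay = np.zeros(n_frames)
    # target at origin: angle from approacher to target is 180 degrees
    heading_a = wrap_angle(180.0 + bearings)
    step = (start_distance - stop_distance) / (n_frames - 1)
    speed_a = np.full(n_frames, step / dt)
    t_idx = np.arange(n_frames)
    approacher = Trajectory(
        t=t_idx, x=ax, y=ay, heading=heading_a, speed=speed_a,
        turn=np.concatenate([[0.0], wrap_angle(np.diff(heading_a)) / dt]),
    )
    target = Trajectory(
        t=t_idx,
        x=np.zeros(n_frames),
        y=np.zeros(n_frames),
        heading=np.full(n_frames, 90.0),
        speed=np.zeros(n_frames),
        turn=np.zeros(n_frames),
    )
    return DyadTrial(
        fish_a=approacher,
        fish_b=target,
        pair_id=pair_id,
        frame_interval_ms=config.frame_interval_ms,
    )


def generate_coupled_symbols(
    K: int, n: int, coupling: float, seed: int = 0
) -> tuple[SymbolSeries, SymbolSeries]:
    """(leader, follower) symbol pair with a known lag-1 copy channel.

    The leader is i.i.d. uniform on {0..K-1}; at each step the follower
    copies the leader's previous symbol with probability ``coupling`` and
    otherwise draws uniformly. The true leader-to-follower TE is
    :func:`coupled_symbols_true_te`.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    leader = rng.integers(0, K, size=n)
    follower = rng.integers(0, K, size=n)
    copy = rng.random(n) < coupling
    follower[1:][copy[1:]] = leader[:-1][copy[1:]]
    return SymbolSeries(leader, K), SymbolSeries(follower, K)


def coupled_symbols_true_te(K: int, coupling: float) -> float:
    """Closed-form TE (bits) of the lag-1 copy channel.

    The follower's symbol is independent of its own past, so
    TE = H(follower) - H(follower | leader's previous symbol)
       = log2 K + p_hit*log2(p_hit) + (K-1)*p_miss*log2(p_miss),
    with p_hit = coupling + (1-coupling)/K and p_miss = (1-coupling)/K.
    """
    p_hit = coupling + (1.0 - coupling) / K
    p_miss = (1.0 - coupling) / K
    h_cond = 0.0
    if p_hit > 0:
        h_cond -= p_hit * math.log2(p_hit)
    if p_miss > 0:
        h_cond -= (K - 1) * p_miss * math.log2(p_miss)
    return math.log2(K) - h_cond


# --- canned fixture suite -------------------------------------------------

def right_to_binocular_profile(progress: float) -> float:
    """Bearing profile of a successful approach: the target starts in the
    right monocular field and is brought into the binocular field."""
    return 60.0 * max(0.0, 1.0 - 2.0 * progress)


def left_persistent_profile(progress: float) -> float:
    """Bearing profile of a failing approach that keeps the target in the
    left monocular field throughout."""
    return -60.0


def make_fixture_trials(seed: int = 0, n_frames: int = 2000) -> dict[str, DyadTrial]:
    """The standard synthetic fixture suite, keyed by name."""
    config = ArenaProtocolConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    fixtures = {
        "null_dyad": generate_dyad(
            SimParams(n_frames=n_frames, seed=seeds[0]), config, pair_id="null_dyad"
        ),
        "follower_dyad": generate_dyad(
            SimParams(
                n_frames=n_frames, seed=seeds[1],
                attraction_gain=0.05, coupling_gain=0.8,
            ),
            config,
            pair_id="follower_dyad",
        ),
        "left_biased_dyad": generate_dyad(
            SimParams(
                n_frames=n_frames, seed=seeds[2],
                attraction_gain=0.15, lateral_bias=45.0,
            ),
            config,
            pair_id="left_biased_dyad",
        ),
        "approach_right_to_binocular": generate_scripted_approach(
            100.0, 13.0, right_to_binocular_profile, config, n_frames=80,
            pair_id="approach_right_to_binocular",
        ),
        "approach_left_persistent": generate_scripted_approach(
            100.0, 40.0, left_persistent_profile, config, n_frames=80,
            pair_id="approach_left_persistent",
        ),
        "bite_block": generate_scripted_approach(
            60.0, 13.0,
            lambda p: 0.0, config, n_frames=40, pair_id="bite_block",
        ),
    }
    return fixtures
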