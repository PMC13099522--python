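"""Approach-episode extraction from the mutual-distance series.

An approach made by fish A is a span of frames in which (1) the mutual
distance keeps reducing, (2) A's episode-mean speed exceeds B's, and
(3) B stays within ±90° of A's heading throughout. Candidate windows run
from each distance peak to the next valley; within a window, the maximal
qualifying sub-spans are emitted. Each frame belongs to at most one fish's
episode: when both fish qualify on overlapping frames, the faster fish
(mean speed over the contested frames) keeps them, and an exact speed tie
assigns them to neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ArenaProtocolConfig
from .geometry import BiteEvent, bearing_series, classify_views, detect_bites
from .trial import DyadTrial


@dataclass
class ApproachEpisode:
    """One detected approach, attributed to a single fish."""

    approacher: str
    start_t: int
    end_t: int
    remaining_distance: float
    view_labels: np.ndarray  # per-frame ViewLabel codes of approacher -> target
    terminal_bite: bool = False

    @property
    def n_frames(self) -> int:
        return self.end_t - self.start_t + 1

    def duration_s(self, frame_interval_ms: float = 100.0) -> float:
        return self.n_frames * frame_interval_ms / 1000.0


def mutual_distance_series(trial: DyadTrial) -> np.ndarray:
    """Per-frame Euclidean inter-fish distance."""
    return np.hypot(trial.fish_a.x - trial.fish_b.x, trial.fish_a.y - trial.fish_b.y)


def find_distance_extrema(
    series, min_prominence: float = 0.0
) -> list[tuple[int, str]]:
    """Alternating (index, 'peak'|'valley') extrema of a distance series.

    Plateaus count once, at their first frame; a monotone run reaching a
    boundary makes that endpoint an extremum. A constant series has no
    extrema. Pairs of adjacent extrema whose amplitude falls below
    ``min_prominence`` are merged away.
    """
    d = np.asarray(series, dtype=float)
    if len(d) < 3:
        raise ValueError("series must have at least 3 frames")
    diffs = np.diff(d)
    nz = np.flatnonzero(diffs)
    if len(nz) == 0:
        return []
    ext: list[tuple[int, str]] = []
    first_sign = np.sign(diffs[nz[0]])
    ext.append((0, "peak" if first_sign < 0 else "valley"))
    prev_sign = first_sign
    prev_j = nz[0]
    for j in nz[1:]:
        sign = np.sign(diffs[j])
        if sign != prev_sign:
            # turning point: first frame after the last move in the old
            # direction (= first frame of any plateau at the turn)
            ext.append((int(prev_j) + 1, "peak" if prev_sign > 0 else "valley"))
            prev_sign = sign
        prev_j = j
    ext.append((len(d) - 1, "peak" if prev_sign > 0 else "valley"))
    if min_prominence > 0:
        ext = _prune_extrema(ext, d, min_prominence)
    return ext


def _prune_extrema(ext, d, min_prominence):
    ext = list(ext)
    while len(ext) >= 2:
        amps = [abs(d[ext[i + 1][0]] - d[ext[i][0]]) for i in range(len(ext) - 1)]
        m = int(np.argmin(amps))
        if amps[m] >= min_prominence:
            break
        del ext[m : m + 2]
        # collapse any consecutive same-kind extrema, keeping the extremer
        i = 0
        while i < len(ext) - 1:
            (ia, ka), (ib, kb) = ext[i], ext[i + 1]
            if ka == kb:
                if ka == "peak":
                    keep = i if d[ia] >= d[ib] else i + 1
                else:
                    keep = i if d[ia] <= d[ib] else i + 1
                del ext[i + (1 if keep == i else 0)]
            else:
                i += 1
    return ext


def _maximal_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True in a boolean array."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def _split_non_increasing(lo: int, hi: int, d: np.ndarray) -> list[tuple[int, int]]:
    """Split [lo, hi] at frames where the distance rises."""
    if hi <= lo:
        return []
    rising = np.flatnonzero(np.diff(d[lo : hi + 1]) > 0)
    if len(rising) == 0:
        return [(lo, hi)]
    spans, start = [], lo
    for r in rising:
        spans.append((start, lo + int(r)))
        start = lo + int(r) + 1
    spans.append((start, hi))
    return spans


def detect_approaches(
    trial: DyadTrial,
    config: ArenaProtocolConfig,
    min_prominence: float = 0.0,
    bites: list[BiteEvent] | None = None,
) -> list[ApproachEpisode]:
    """Extract approach episodes for both fish of a trial."""
    d = mutual_distance_series(trial)
    ext = find_distance_extrema(d, min_prominence)
    windows = [
        (ext[i][0], ext[i + 1][0])
        for i in range(len(ext) - 1)
        if ext[i][1] == "peak" and ext[i + 1][1] == "valley"
    ]
    bear_ab = bearing_series(trial.fish_a, trial.fish_b)
    bear_ba = bearing_series(trial.fish_b, trial.fish_a)
    half = config.toward_range_halfwidth
    with np.errstate(invalid="ignore"):
        facing = {
            trial.id_a: np.abs(bear_ab) <= half,
            trial.id_b: np.abs(bear_ba) <= half,
        }
    speeds = {trial.id_a: trial.fish_a.speed, trial.id_b: trial.fish_b.speed}
    bearings = {trial.id_a: bear_ab, trial.id_b: bear_ba}
    min_len = config.min_approach_frames
    if bites is None:
        bites = detect_bites(trial, config)
    bite_frames = {trial.id_a: set(), trial.id_b: set()}
    for ev in bites:
        bite_frames[ev.biter].add(ev.t)

    def qualifies(fish: str, lo: int, hi: int) -> bool:
        other = trial.opponent(fish)
        if hi - lo + 1 < min_len or not d[lo] > d[hi]:
            return False
        return float(np.mean(speeds[fish][lo : hi + 1])) > float(
            np.mean(speeds[other][lo : hi + 1])
        )

    episodes: list[ApproachEpisode] = []
    for wlo, whi in windows:
        masks = {}
        for fish in (trial.id_a, trial.id_b):
            mask = np.zeros(whi - wlo + 1, dtype=bool)
            window_facing = facing[fish][wlo : whi + 1]
            for rlo, rhi in _maximal_runs(window_facing):
                for slo, shi in _split_non_increasing(wlo + rlo, wlo + rhi, d):
                    if qualifies(fish, slo, shi):
                        mask[slo - wlo : shi - wlo + 1] = True
            masks[fish] = mask
        # exclusivity: contested frames go to the faster fish over those frames
        contested = masks[trial.id_a] & masks[trial.id_b]
        for clo, chi in _maximal_runs(contested):
            lo, hi = wlo + clo, wlo + chi
            sa = float(np.mean(speeds[trial.id_a][lo : hi + 1]))
            sb = float(np.mean(speeds[trial.id_b][lo : hi + 1]))
            if sa > sb:
                masks[trial.id_b][clo : chi + 1] = False
            elif sb > sa:
                masks[trial.id_a][clo : chi + 1] = False
            else:
                masks[trial.id_a][clo : chi + 1] = False
                masks[trial.id_b][clo : chi + 1] = False
        for fish in (trial.id_a, trial.id_b):
            for rlo, rhi in _maximal_runs(masks[fish]):
                lo, hi = wlo + rlo, wlo + rhi
                if not qualifies(fish, lo, hi):
                    continue
                labels = classify_views(bearings[fish][lo : hi + 1], config)
                terminal = any(
                    t in bite_frames[fish] for t in range(max(lo, hi - 1), min(hi + 2, trial.n_frames))
                )
                episodes.append(
                    ApproachEpisode(
                        approacher=fish,
                        start_t=lo,
                        end_t=hi,
                        remaining_distance=float(d[hi]),
                        view_labels=labels,
                        terminal_bite=terminal,
                    )
                )
    episodes.sort(key=lambda e: (e.start_t, e.approacher))
    return episodes


def bites_per_approach(
    trial: DyadTrial,
    episodes: list[ApproachEpisode],
    bites: list[BiteEvent],
) -> dict[str, float | None]:
    """Per-fish ratio of bite events to approach episodes.

    A fish with zero approaches gets ``None`` (undefined, reported as
    missing rather than zero).
    """
    out: dict[str, float | None] = {}
    for fish in (trial.id_a, trial.id_b):
        n_app = sum(1 for e in episodes if e.approacher == fish)
        n_bites = sum(1 for b in bites if b.biter == fish)
        out[fish] = (n_bites / n_app) if n_app > 0 else None
    return out
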