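"""Trial-level interaction statistics.

* attraction: fractional reduction of the observed mean inter-fish
  distance relative to a shuffled-position null (10 random permutations of
  one fish's position frames).
* eye-use: LEP / FBVP / REP share one denominator (left + right +
  binocular frame counts, blind excluded); the left eye index LEI uses
  monocular frames only, (N_left - N_right) / (N_left + N_right).
* distance-binned profiles: eye percentages per 10-unit mutual-distance
  bin over [0, 200).
* proximity split: approaches ending at distance <= 20 (high proximity)
  vs > 100 (low proximity).

Undefined values (empty denominators, empty bins) propagate as ``None`` /
NaN, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .approach import ApproachEpisode, bites_per_approach, detect_approaches, mutual_distance_series
from .config import ArenaProtocolConfig
from .geometry import (
    ViewLabel,
    attack_posture_rate,
    bearing_series,
    center_occupancy_rate,
    classify_views,
    detect_bites,
    near_rate,
)
from .te import TEResult, te_bundle
from .trial import DyadTrial


@dataclass(frozen=True)
class EyeUseCounts:
    """Frame counts per view label over a frame set."""

    n_left: int
    n_right: int
    n_binocular: int
    n_blind: int = 0

    def __post_init__(self) -> None:
        if min(self.n_left, self.n_right, self.n_binocular, self.n_blind) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return self.n_left + self.n_right + self.n_binocular + self.n_blind

    @classmethod
    def from_labels(cls, labels) -> "EyeUseCounts":
        labels = np.asarray(labels)
        return cls(
            n_left=int(np.count_nonzero(labels == ViewLabel.LEFT)),
            n_right=int(np.count_nonzero(labels == ViewLabel.RIGHT)),
            n_binocular=int(np.count_nonzero(labels == ViewLabel.BINOCULAR)),
            n_blind=int(np.count_nonzero(labels == ViewLabel.BLIND)),
        )


def attraction(
    trial: DyadTrial,
    n_shuffles: int = 10,
    seed: int | np.random.Generator = 0,
    shuffle_fish: str = "b",
) -> float:
    """Shuffle-null attraction statistic.

    (mean(dist_shuffled) - dist_real) / mean(dist_shuffled), where each
    shuffled distance is the mean inter-fish distance after a uniform
    random permutation of one fish's position frames. ``shuffle_fish`` is
    'b' (default), 'a', or 'both' (average of both choices). Deterministic
    given the seed.
    """
    if trial.n_frames < 2:
        raise ValueError("attraction needs at least 2 frames")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pa = trial.fish_a.positions
    pb = trial.fish_b.positions
    dist_real = float(np.mean(np.hypot(*(pa - pb).T)))

    def one_side(moving, still):
        means = np.empty(n_shuffles)
        for k in range(n_shuffles):
            perm = rng.permutation(len(moving))
            diff = moving[perm] - still
            means[k] = np.mean(np.hypot(diff[:, 0], diff[:, 1]))
        return means

    if shuffle_fish == "b":
        shuffle_means = one_side(pb, pa)
    elif shuffle_fish == "a":
        shuffle_means = one_side(pa, pb)
    elif shuffle_fish == "both":
        shuffle_means = np.concatenate([one_side(pb, pa), one_side(pa, pb)])
    else:
        raise ValueError("shuffle_fish must be 'a', 'b' or 'both'")
    mean_shuffled = float(np.mean(shuffle_means))
    if mean_shuffled == 0.0:
        return 0.0
    # numerator via per-shuffle differences so that shuffle-invariant
    # inputs (e.g. a time-constant opponent) give exactly zero
    return float(np.mean(shuffle_means - dist_real)) / mean_shuffled


def eye_percentages(counts: EyeUseCounts) -> tuple[float, float, float] | None:
    """(LEP, FBVP, REP) percentages with blind frames excluded.

    Returns None for an all-blind frame set (undefined)."""
    denom = counts.n_left + counts.n_right + counts.n_binocular
    if denom == 0:
        return None
    return (
        100.0 * counts.n_left / denom,
        100.0 * counts.n_binocular / denom,
        100.0 * counts.n_right / denom,
    )


def left_eye_index(counts: EyeUseCounts) -> float | None:
    """LEI in [-1, +1]; binocular and blind frames are excluded.

    Returns None when there are no monocular frames."""
    denom = counts.n_left + counts.n_right
    if denom == 0:
        return None
    return (counts.n_left - counts.n_right) / denom


def fbvp_by_distance(
    distances, labels, config: ArenaProtocolConfig
) -> pd.DataFrame:
    """Per-distance-bin eye percentages.

    Frames are grouped by mutual distance into ``fbv_n_bins`` bins of width
    ``fbv_bin_width`` over [0, n*width); per-bin LEP/FBVP/REP are computed
    with the common non-blind denominator. Empty (or all-blind) bins hold
    NaN. Columns: bin_lo, bin_hi, lep, fbvp, rep, n_frames.
    """
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    if len(distances) != len(labels):
        raise ValueError("distances and labels must align")
    width, n_bins = config.fbv_bin_width, config.fbv_n_bins
    rows = []
    bin_idx = np.floor(distances / width).astype(int)
    for k in range(n_bins):
        in_bin = bin_idx == k
        counts = EyeUseCounts.from_labels(labels[in_bin])
        pct = eye_percentages(counts)
        lep, fbvp, rep = pct if pct is not None else (np.nan, np.nan, np.nan)
        rows.append(
            {
                "bin_lo": k * width,
                "bin_hi": (k + 1) * width,
                "lep": lep,
                "fbvp": fbvp,
                "rep": rep,
                "n_frames": int(np.count_nonzero(in_bin)),
            }
        )
    return pd.DataFrame(rows)


def trial_fbvp_by_distance(
    trial: DyadTrial, fish: str, config: ArenaProtocolConfig
) -> pd.DataFrame:
    """Distance-binned eye percentages over all frames of one fish."""
    obs = trial.trajectory(fish)
    tgt = trial.trajectory(trial.opponent(fish))
    labels = classify_views(bearing_series(obs, tgt), config)
    return fbvp_by_distance(mutual_distance_series(trial), labels, config)


def episode_fbvp_by_distance(
    trial: DyadTrial,
    episodes: list[ApproachEpisode],
    config: ArenaProtocolConfig,
    fish: str | None = None,
) -> pd.DataFrame:
    """Distance-binned eye percentages pooled over approach frames."""
    d = mutual_distance_series(trial)
    dist_parts, label_parts = [], []
    for ep in episodes:
        if fish is not None and ep.approacher != fish:
            continue
        dist_parts.append(d[ep.start_t : ep.end_t + 1])
        label_parts.append(ep.view_labels)
    if not dist_parts:
        dist_parts, label_parts = [np.empty(0)], [np.empty(0, dtype=int)]
    return fbvp_by_distance(
        np.concatenate(dist_parts), np.concatenate(label_parts), config
    )


def proximity_split(
    episodes: list[ApproachEpisode], config: ArenaProtocolConfig
) -> tuple[list[ApproachEpisode], list[ApproachEpisode]]:
    """(high-proximity, low-proximity) episode subsets by remaining distance.

    High: remaining distance <= high_proximity_threshold (20 units, just
    under a body length); low: > low_proximity_threshold (100 units, the
    arena radius). Episodes in between belong to neither subset.
    """
    high = [e for e in episodes if e.remaining_distance <= config.high_proximity_threshold]
    low = [e for e in episodes if e.remaining_distance > config.low_proximity_threshold]
    return high, low


def episodes_table(
    episodes: list[ApproachEpisode], frame_interval_ms: float = 100.0
) -> pd.DataFrame:
    """One row per approach episode with its eye-use summary.

    Columns: approacher, start_frame, end_frame, duration_s,
    remaining_distance, terminal_bite, lep, fbvp, rep, lei.
    """
    rows = []
    for ep in episodes:
        counts = EyeUseCounts.from_labels(ep.view_labels)
        pct = eye_percentages(counts)
        lep, fbvp, rep = pct if pct is not None else (np.nan, np.nan, np.nan)
        lei = left_eye_index(counts)
        rows.append(
            {
                "approacher": ep.approacher,
                "start_frame": ep.start_t,
                "end_frame": ep.end_t,
                "duration_s": ep.duration_s(frame_interval_ms),
                "remaining_distance": ep.remaining_distance,
                "terminal_bite": ep.terminal_bite,
                "lep": lep,
                "fbvp": fbvp,
                "rep": rep,
                "lei": lei if lei is not None else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "approacher", "start_frame", "end_frame", "duration_s",
            "remaining_distance", "terminal_bite", "lep", "fbvp", "rep", "lei",
        ],
    )


def episode_eye_counts(episodes: list[ApproachEpisode], fish: str | None = None) -> EyeUseCounts:
    """Pooled eye-use counts over the frames of a set of episodes."""
    labels = [e.view_labels for e in episodes if fish is None or e.approacher == fish]
    if not labels:
        return EyeUseCounts(0, 0, 0, 0)
    return EyeUseCounts.from_labels(np.concatenate(labels))


@dataclass
class FishMetrics:
    """Per-fish slice of the trial statistics."""

    fish_id: str
    attack_posture_rate: float
    center_occupancy: float
    lep: float | None
    fbvp: float | None
    rep: float | None
    lei: float | None
    approach_lep: float | None
    approach_fbvp: float | None
    approach_rep: float | None
    approach_lei: float | None
    n_approaches: int
    n_bites: int
    bites_per_approach: float | None


@dataclass
class TrialMetrics:
    """The full per-trial statistic bundle."""

    pair_id: str
    condition: str
    mean_mutual_distance: float
    near_rate: float
    attraction: float
    te: dict[str, TEResult]
    fish: dict[str, FishMetrics]


def compute_trial_metrics(
    trial: DyadTrial,
    config: ArenaProtocolConfig,
    seed: int = 0,
    min_prominence: float = 0.0,
) -> TrialMetrics:
    """Run the whole per-trial analysis pipeline."""
    d = mutual_distance_series(trial)
    bites = detect_bites(trial, config)
    episodes = detect_approaches(trial, config, min_prominence, bites=bites)
    bpa = bites_per_approach(trial, episodes, bites)
    per_fish: dict[str, FishMetrics] = {}
    for fid in (trial.id_a, trial.id_b):
        obs = trial.trajectory(fid)
        tgt = trial.trajectory(trial.opponent(fid))
        labels = classify_views(bearing_series(obs, tgt), config)
        counts = EyeUseCounts.from_labels(labels)
        pct = eye_percentages(counts)
        ep_counts = episode_eye_counts(episodes, fid)
        ep_pct = eye_percentages(ep_counts)
        per_fish[fid] = FishMetrics(
            fish_id=fid,
            attack_posture_rate=attack_posture_rate(trial, fid, config),
            center_occupancy=center_occupancy_rate(trial, fid, config),
            lep=pct[0] if pct else None,
            fbvp=pct[1] if pct else None,
            rep=pct[2] if pct else None,
            lei=left_eye_index(counts),
            approach_lep=ep_pct[0] if ep_pct else None,
            approach_fbvp=ep_pct[1] if ep_pct else None,
            approach_rep=ep_pct[2] if ep_pct else None,
            approach_lei=left_eye_index(ep_counts),
            n_approaches=sum(1 for e in episodes if e.approacher == fid),
            n_bites=sum(1 for b in bites if b.biter == fid),
            bites_per_approach=bpa[fid],
        )
    return TrialMetrics(
        pair_id=trial.pair_id,
        condition=trial.condition.value,
        mean_mutual_distance=float(np.mean(d)),
        near_rate=near_rate(trial, config),
        attraction=attraction(trial, seed=seed),
        te=te_bundle(trial),
        fish=per_fish,
    )


def metrics_table(all_metrics: list[TrialMetrics]) -> pd.DataFrame:
    """One row per (trial, fish), ready for group comparisons."""
    rows = []
    for m in all_metrics:
        for idx, (fid, fm) in enumerate(m.fish.items()):
            is_a = idx == 0  # insertion order: fish_a first
            rows.append(
                {
                    "pair_id": m.pair_id,
                    "condition": m.condition,
                    "fish_id": fid,
                    "mean_mutual_distance": m.mean_mutual_distance,
                    "near_rate": m.near_rate,
                    "attraction": m.attraction,
                    "attack_posture_rate": fm.attack_posture_rate,
                    "center_occupancy": fm.center_occupancy,
                    "lep": fm.lep,
                    "fbvp": fm.fbvp,
                    "rep": fm.rep,
                    "lei": fm.lei,
                    "approach_lep": fm.approach_lep,
                    "approach_fbvp": fm.approach_fbvp,
                    "approach_rep": fm.approach_rep,
                    "approach_lei": fm.approach_lei,
                    "n_approaches": fm.n_approaches,
                    "n_bites": fm.n_bites,
                    "bites_per_approach": fm.bites_per_approach,
                    "te_merged": m.te["merged"].te_ab if is_a else m.te["merged"].te_ba,
                    "te_speed": m.te["speed"].te_ab if is_a else m.te["speed"].te_ba,
                    "te_turn": m.te["turn"].te_ab if is_a else m.te["turn"].te_ba,
                    "delta_te_speed": m.te["speed"].delta_te,
                }
            )
    return pd.DataFrame(rows)
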