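"""Approach-episode extraction: extrema, assignment, exclusivity."""

import numpy as np
import pytest

from dyadvr import (
    SimParams,
    ViewLabel,
    bites_per_approach,
    detect_approaches,
    detect_bites,
    find_distance_extrema,
    generate_dyad,
    generate_scripted_approach,
    mutual_distance_series,
)
from dyadvr.geometry import BiteEvent

from conftest import build_trial


class TestMutualDistance:
    def test_start_positions_are_100_apart(self, config):
        trial = generate_dyad(SimParams(n_frames=5, seed=0))
        assert mutual_distance_series(trial)[0] == pytest.approx(100.0)

    def test_coincident_positions_give_zero(self, config):
        trial = build_trial(
            xa=[1.0, 1.0, 1.0], ya=[2.0, 2.0, 2.0], ha=[0, 0, 0], sa=[0, 0, 0],
            xb=[1.0, 1.0, 1.0], yb=[2.0, 2.0, 2.0], hb=[0, 0, 0], sb=[0, 0, 0],
        )
        np.testing.assert_array_equal(mutual_distance_series(trial), 0.0)

    def test_matches_per_frame_hypot_oracle(self):
        rng = np.random.default_rng(3)
        n = 50
        xa, ya, xb, yb = rng.uniform(-70, 70, size=(4, n))
        trial = build_trial(
            xa=xa, ya=ya, ha=np.zeros(n), sa=np.zeros(n),
            xb=xb, yb=yb, hb=np.zeros(n), sb=np.zeros(n),
        )
        d = mutual_distance_series(trial)
        for i in range(n):
            expected = ((xa[i] - xb[i]) ** 2 + (ya[i] - yb[i]) ** 2) ** 0.5
            assert d[i] == pytest.approx(expected, abs=1e-12)


class TestDistanceExtrema:
    def test_monotone_decreasing(self):
        ext = find_distance_extrema(np.linspace(100, 10, 20))
        assert ext == [(0, "peak"), (19, "valley")]

    def test_monotone_increasing(self):
        ext = find_distance_extrema(np.linspace(10, 100, 20))
        assert ext == [(0, "valley"), (19, "peak")]

    def test_constant_series_has_no_extrema(self):
        assert find_distance_extrema(np.full(10, 42.0)) == []

    def test_triangle_wave(self):
        series = np.concatenate(
            [np.linspace(0, 10, 6), np.linspace(10, 0, 6)[1:],
             np.linspace(0, 10, 6)[1:]]
        )
        ext = find_distance_extrema(series)
        assert ext == [(0, "valley"), (5, "peak"), (10, "valley"), (15, "peak")]

    def test_plateau_counts_at_first_frame(self):
        series = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0])
        ext = find_distance_extrema(series)
        assert ext == [(0, "valley"), (2, "peak"), (6, "valley")]

    def test_noisy_sinusoid_matches_neighbor_scan_oracle(self):
        rng = np.random.default_rng(11)
        t = np.arange(400)
        series = np.sin(t / 15.0) + 0.05 * rng.standard_normal(400)
        ext = find_distance_extrema(series)
        # independent oracle: strict neighbor comparison (no ties in
        # continuous noise) plus monotone-run endpoints
        oracle = []
        if series[1] < series[0]:
            oracle.append((0, "peak"))
        else:
            oracle.append((0, "valley"))
        for i in range(1, 399):
            if series[i] > series[i - 1] and series[i] > series[i + 1]:
                oracle.append((i, "peak"))
            elif series[i] < series[i - 1] and series[i] < series[i + 1]:
                oracle.append((i, "valley"))
        if series[-1] > series[-2]:
            oracle.append((399, "peak"))
        else:
            oracle.append((399, "valley"))
        assert ext == oracle

    def test_alternation_invariant(self):
        rng = np.random.default_rng(5)
        series = rng.uniform(0, 100, 200)
        ext = find_distance_extrema(series)
        kinds = [k for _, k in ext]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_prominence_merges_small_wiggles(self):
        series = np.array([10.0, 8.0, 8.4, 6.0, 6.2, 4.0, 2.0])
        raw = find_distance_extrema(series)
        assert len(raw) == 6
        pruned = find_distance_extrema(series, min_prominence=1.0)
        assert pruned == [(0, "peak"), (6, "valley")]

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            find_distance_extrema([1.0, 2.0])


class TestDetectApproaches:
    def test_straight_approach_to_static_target(self, config):
        trial = generate_scripted_approach(90.0, 30.0, lambda p: 0.0, config,
                                           n_frames=30)
        episodes = detect_approaches(trial, config)
        assert len(episodes) == 1
        ep = episodes[0]
        assert ep.approacher == "a"
        assert (ep.start_t, ep.end_t) == (0, 29)
        assert ep.remaining_distance == pytest.approx(30.0)
        assert not ep.terminal_bite

    def test_mutual_approach_assigned_to_faster_fish(self, config):
        n = 20
        xa = np.linspace(-80, -40, n)   # A moves +x at 2 units/frame
        xb = np.linspace(80, 60, n)     # B moves -x at 1 unit/frame
        trial = build_trial(
            xa=xa, ya=np.zeros(n), ha=np.zeros(n), sa=np.full(n, 20.0),
            xb=xb, yb=np.zeros(n), hb=np.full(n, 180.0), sb=np.full(n, 10.0),
        )
        episodes = detect_approaches(trial, config)
        assert [e.approacher for e in episodes] == ["a"]

    def test_equal_speeds_yield_no_approach(self, config):
        n = 20
        xa = np.linspace(-80, -60, n)
        xb = np.linspace(80, 60, n)
        trial = build_trial(
            xa=xa, ya=np.zeros(n), ha=np.zeros(n), sa=np.full(n, 10.0),
            xb=xb, yb=np.zeros(n), hb=np.full(n, 180.0), sb=np.full(n, 10.0),
        )
        assert detect_approaches(trial, config) == []

    def test_target_behind_approacher_not_an_approach(self, config):
        """Distance shrinks and A is faster, but A faces away from B."""
        n = 15
        xa = np.linspace(-80, -40, n)
        trial = build_trial(
            xa=xa, ya=np.zeros(n), ha=np.full(n, 180.0), sa=np.full(n, 20.0),
            xb=np.full(n, 50.0), yb=np.zeros(n), hb=np.full(n, 90.0),
            sb=np.zeros(n),
        )
        assert detect_approaches(trial, config) == []

    def test_episode_distances_non_increasing(self, config):
        for seed in range(5):
            trial = generate_dyad(
                SimParams(n_frames=800, seed=seed, attraction_gain=0.1)
            )
            d = mutual_distance_series(trial)
            for ep in detect_approaches(trial, config):
                span = d[ep.start_t : ep.end_t + 1]
                assert np.all(np.diff(span) <= 0)
                assert span[0] > span[-1]

    def test_episode_exclusivity(self, config):
        """The per-frame approacher assignment is a partial function."""
        for seed in range(10):
            trial = generate_dyad(
                SimParams(n_frames=600, seed=100 + seed, attraction_gain=0.15)
            )
            owner = np.zeros(trial.n_frames, dtype=int)
            for ep in detect_approaches(trial, config):
                owner[ep.start_t : ep.end_t + 1] += 1
            assert owner.max() <= 1

    def test_view_labels_cover_episode(self, config):
        trial = generate_scripted_approach(
            90.0, 20.0, lambda p: 60.0 * (1 - p), config, n_frames=40
        )
        episodes = detect_approaches(trial, config)
        assert len(episodes) == 1
        assert len(episodes[0].view_labels) == episodes[0].n_frames


class TestBitesPerApproach:
    def test_ratio_arithmetic(self, config):
        trial = generate_scripted_approach(90.0, 30.0, lambda p: 0.0, config,
                                           n_frames=30)
        episodes = detect_approaches(trial, config)
        fake = [
            BiteEvent(t=29, biter="a", bitten="b"),
            BiteEvent(t=15, biter="a", bitten="b"),
        ]
        ratios = bites_per_approach(trial, episodes * 4, fake)
        assert ratios["a"] == pytest.approx(0.5)
        assert ratios["b"] is None  # zero approaches -> missing, not 0

    def test_zero_bites_is_zero(self, config):
        trial = generate_scripted_approach(90.0, 30.0, lambda p: 0.0, config,
                                           n_frames=30)
        episodes = detect_approaches(trial, config)
        ratios = bites_per_approach(trial, episodes, [])
        assert ratios["a"] == 0.0

    def test_terminal_bite_flagged(self, config):
        trial = generate_scripted_approach(60.0, 13.0, lambda p: 0.0, config,
                                           n_frames=40)
        episodes = detect_approaches(trial, config)
        assert len(episodes) == 1
        assert episodes[0].terminal_bite
        bites = detect_bites(trial, config)
        assert len(bites) == 1 and bites[0].biter == "a"
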