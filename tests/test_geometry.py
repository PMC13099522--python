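"""Per-frame geometric classifiers: bearing, view fields, posture, bites."""

import numpy as np
import pytest

from dyadvr import (
    DegenerateGeometryError,
    FishFrame,
    ViewLabel,
    attack_posture_rate,
    center_occupancy_rate,
    classify_view,
    classify_views,
    detect_bites,
    is_attack_posture,
    near_rate,
    relative_bearing,
)

from conftest import build_trial, constant_trial


def ff(x=0.0, y=0.0, heading=0.0, speed=0.0, t=0):
    return FishFrame(t=t, x=x, y=y, heading=heading, speed=speed, turn=0.0)


class TestRelativeBearing:
    def test_dead_ahead(self):
        assert relative_bearing(ff(heading=0.0), (10.0, 0.0)) == pytest.approx(0.0)

    def test_left_is_negative(self):
        assert relative_bearing(ff(heading=0.0), (0.0, 10.0)) == pytest.approx(-90.0)
        assert relative_bearing(ff(heading=0.0), (0.0, -10.0)) == pytest.approx(90.0)

    def test_coincident_positions_raise(self):
        with pytest.raises(DegenerateGeometryError):
            relative_bearing(ff(x=1.0, y=2.0), (1.0, 2.0))

    def test_matches_vector_cross_product_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            ox, oy, tx, ty = rng.uniform(-90, 90, size=4)
            heading = rng.uniform(-179.99, 180)
            if (ox, oy) == (tx, ty):
                continue
            got = relative_bearing(ff(x=ox, y=oy, heading=heading), (tx, ty))
            ux, uy = np.cos(np.radians(heading)), np.sin(np.radians(heading))
            wx, wy = tx - ox, ty - oy
            cross = ux * wy - uy * wx
            dot = ux * wx + uy * wy
            expected = -np.degrees(np.arctan2(cross, dot))
            if expected == -180.0:
                expected = 180.0
            assert got == pytest.approx(expected, abs=1e-9)


class TestClassifyView:
    @pytest.mark.parametrize(
        "bearing,label",
        [
            (0.0, ViewLabel.BINOCULAR),
            (-90.0, ViewLabel.LEFT),
            (90.0, ViewLabel.RIGHT),
            (180.0, ViewLabel.BLIND),
            (-135.0, ViewLabel.LEFT),
            (-30.0, ViewLabel.BINOCULAR),
            (30.0, ViewLabel.BINOCULAR),
            (135.0, ViewLabel.RIGHT),
            (-135.001, ViewLabel.BLIND),
            (135.001, ViewLabel.BLIND),
        ],
    )
    def test_ranges_and_boundaries(self, config, bearing, label):
        assert classify_view(bearing, config) is label

    def test_total_partition(self, config):
        """Every bearing in (-180, 180] gets exactly one label."""
        grid = np.linspace(-179.999, 180.0, 14401)
        labels = classify_views(grid, config)
        in_left = (grid >= -135) & (grid < -30)
        in_bin = (grid >= -30) & (grid <= 30)
        in_right = (grid > 30) & (grid <= 135)
        membership = in_left.astype(int) + in_bin.astype(int) + in_right.astype(int)
        assert membership.max() <= 1
        np.testing.assert_array_equal(labels == ViewLabel.BLIND, membership == 0)
        np.testing.assert_array_equal(labels == ViewLabel.LEFT, in_left)
        np.testing.assert_array_equal(labels == ViewLabel.BINOCULAR, in_bin)
        np.testing.assert_array_equal(labels == ViewLabel.RIGHT, in_right)


class TestAttackPosture:
    def test_heading_at_center_any_distance(self, config):
        for d in (5.0, 30.0, 150.0):
            assert is_attack_posture(ff(x=-d, heading=0.0), ff(), config)

    def test_heading_away(self, config):
        assert not is_attack_posture(ff(x=-60.0, heading=180.0), ff(), config)

    def test_rotation_translation_invariance(self, config):
        rng = np.random.default_rng(1)
        for _ in range(200):
            ox, oy, tx, ty = rng.uniform(-80, 80, size=4)
            h = rng.uniform(-180, 180)
            base = is_attack_posture(ff(x=ox, y=oy, heading=h), ff(x=tx, y=ty), config)
            phi = rng.uniform(0, 360)
            dx, dy = rng.uniform(-20, 20, size=2)
            c, s = np.cos(np.radians(phi)), np.sin(np.radians(phi))
            rot = lambda x, y: (c * x - s * y + dx, s * x + c * y + dy)
            ox2, oy2 = rot(ox, oy)
            tx2, ty2 = rot(tx, ty)
            moved = is_attack_posture(
                ff(x=ox2, y=oy2, heading=((h + phi + 180) % 360) - 180),
                ff(x=tx2, y=ty2),
                config,
            )
            assert base == moved

    def test_against_dense_ray_sampling_oracle(self, config):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 400:
            ox, oy, tx, ty = rng.uniform(-90, 90, size=4)
            h = rng.uniform(-180, 180)
            obs, tgt = ff(x=ox, y=oy, heading=h), ff(x=tx, y=ty)
            ux, uy = np.cos(np.radians(h)), np.sin(np.radians(h))
            mx, my = ox + 12.5 * ux, oy + 12.5 * uy
            steps = np.linspace(0.0, 500.0, 20001)
            px, py = mx + steps * ux, my + steps * uy
            min_dist = np.min(np.hypot(px - tx, py - ty))
            if abs(min_dist - config.attack_circle_radius) < 0.05:
                continue  # too close to the boundary for a sampled oracle
            assert is_attack_posture(obs, tgt, config) == (
                min_dist <= config.attack_circle_radius
            )
            checked += 1

    def test_rate_on_scripted_fixture(self, config):
        """10 frames, 4 of which head at the opponent -> 40%."""
        headings = np.array([0.0] * 4 + [180.0] * 6)
        trial = build_trial(
            xa=np.full(10, -50.0), ya=np.zeros(10), ha=headings, sa=np.zeros(10),
            xb=np.zeros(10), yb=np.zeros(10), hb=np.full(10, 90.0), sb=np.zeros(10),
        )
        assert attack_posture_rate(trial, "a", config) == pytest.approx(40.0)

    def test_rate_extremes(self, config):
        toward = constant_trial(5, (-50, 0), (0, 0), heading_a=0.0)
        away = constant_trial(5, (-50, 0), (0, 0), heading_a=180.0)
        assert attack_posture_rate(toward, "a", config) == 100.0
        assert attack_posture_rate(away, "a", config) == 0.0


class TestDetectBites:
    @staticmethod
    def _biter_trial(biter_x, biter_heading=180.0):
        """Opponent fixed at origin heading +y; biter on the +x axis."""
        n = len(biter_x)
        return build_trial(
            xa=np.asarray(biter_x, float), ya=np.zeros(n),
            ha=np.full(n, biter_heading), sa=np.zeros(n),
            xb=np.zeros(n), yb=np.zeros(n), hb=np.full(n, 90.0), sb=np.zeros(n),
        )

    def test_one_event_per_contiguous_block(self, config):
        # mouth is 12.5 ahead; x=13 puts it 0.5 from the mid-body segment
        xs = [30] * 5 + [13] * 5
        bites = detect_bites(self._biter_trial(xs), config)
        assert [(b.t, b.biter) for b in bites] == [(5, "a")]

    def test_two_separated_blocks_two_events(self, config):
        xs = [30, 13, 13, 30, 30, 13, 13, 30]
        bites = detect_bites(self._biter_trial(xs), config)
        assert [(b.t, b.biter) for b in bites] == [(1, "a"), (5, "a")]

    def test_block_at_trial_start_counts(self, config):
        bites = detect_bites(self._biter_trial([13, 13, 30]), config)
        assert [(b.t, b.biter) for b in bites] == [(0, "a")]

    def test_parallel_approach_is_not_a_bite(self, config):
        """Heading parallel to the opponent's body axis: inclination from
        the perpendicular is 90 degrees, beyond the ±75° window."""
        n = 4
        trial = build_trial(
            xa=np.full(n, 0.5), ya=np.full(n, -12.5), ha=np.full(n, 90.0),
            sa=np.zeros(n),
            xb=np.zeros(n), yb=np.zeros(n), hb=np.full(n, 90.0), sb=np.zeros(n),
        )
        # mouth lands at (0.5, 0): touching the mid-body, but the angle fails
        assert detect_bites(trial, config) == []

    def test_outside_midbody_is_not_a_bite(self, config):
        """Mouth touching the opponent's head region, not the mid-body."""
        n = 3
        trial = build_trial(
            xa=np.full(n, 13.0), ya=np.full(n, 8.0), ha=np.full(n, 180.0),
            sa=np.zeros(n),
            xb=np.zeros(n), yb=np.zeros(n), hb=np.full(n, 90.0), sb=np.zeros(n),
        )
        # mouth at (0.5, 8.0): level with the head section, 3.8 units from
        # the end of the central-third mid-body segment (|s| <= 25/6)
        assert detect_bites(trial, config) == []


class TestOccupancyRates:
    def test_near_rate_extremes(self, config):
        far = constant_trial(10, (50, 0), (-50, 0))
        close = constant_trial(10, (5, 0), (-5, 0))
        assert near_rate(far, config) == 0.0
        assert near_rate(close, config) == 100.0

    def test_near_rate_hand_counted(self, config):
        xa = np.array([40.0] * 3 + [80.0] * 7)
        trial = build_trial(
            xa=xa, ya=np.zeros(10), ha=np.zeros(10), sa=np.zeros(10),
            xb=np.zeros(10), yb=np.zeros(10), hb=np.zeros(10), sb=np.zeros(10),
        )
        assert near_rate(trial, config) == pytest.approx(30.0)

    def test_near_rate_boundary_inclusive(self, config):
        at_50 = constant_trial(4, (50, 0), (0, 0))
        assert near_rate(at_50, config) == 100.0

    def test_center_occupancy(self, config):
        at_origin = constant_trial(6, (0, 0), (10, 0))
        at_90 = constant_trial(6, (90, 0), (10, 0))
        assert center_occupancy_rate(at_origin, "a", config) == 100.0
        assert center_occupancy_rate(at_90, "a", config) == 0.0

    def test_center_occupancy_half_and_half(self, config):
        xa = np.array([0.0] * 5 + [90.0] * 5)
        trial = build_trial(
            xa=xa, ya=np.zeros(10), ha=np.zeros(10), sa=np.zeros(10),
            xb=np.full(10, 10.0), yb=np.zeros(10), hb=np.zeros(10),
            sb=np.zeros(10),
        )
        assert center_occupancy_rate(trial, "a", config) == pytest.approx(50.0)

    def test_rates_bounded(self, config):
        from dyadvr import SimParams, generate_dyad

        trial = generate_dyad(SimParams(n_frames=500, seed=9, attraction_gain=0.1))
        for val in (
            near_rate(trial, config),
            center_occupancy_rate(trial, "a", config),
            attack_posture_rate(trial, "b", config),
        ):
            assert 0.0 <= val <= 100.0
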