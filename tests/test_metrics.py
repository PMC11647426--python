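import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import make_traj, stationary_traj
from openfield import metrics as mm
from openfield.core import SessionMetadata
from openfield.simulate import simulate_session


def jittery_traj(seed, n=600, dt=0.1, pause_spans=((100, 250), (400, 480))):
    """Random walk with stationary spans; small tracking jitter everywhere."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0, 0.4, (n, 2))
    for s, e in pause_spans:
        steps[s:e] = 0.0
    center = np.clip(25 + np.cumsum(steps, axis=0), 0, 50)
    center += rng.normal(0, 0.005, (n, 2))
    head = np.clip(center + rng.normal([1.5, 0.0], 0.1, (n, 2)), 0, 50)
    tail = np.clip(center - rng.normal([1.5, 0.0], 0.1, (n, 2)), 0, 50)
    return make_traj(center, head=head, tail=tail, dt=dt)


class TestImmobilitySegmentation:
    def test_stationary_block_detected(self):
        # 10 s still bounded by clear movement
        dt = 0.1
        moving = 25 + np.cumsum(np.full((50, 2), 0.3), axis=0)
        still = np.tile(moving[-1], (100, 1))
        center = np.vstack([moving, still, moving[-1] + np.cumsum(
            np.full((50, 2), -0.3), axis=0)])
        traj = make_traj(center, dt=dt)
        eps = mm.segment_immobility(traj)
        imm = eps.of_kind("immobile")
        assert len(imm) == 1
        assert imm[0].duration == pytest.approx(10.0, abs=0.6)

    def test_short_pause_below_threshold_ignored(self):
        # stationary for exactly 1.5 s < 2 s minimum
        dt = 0.1
        moving = 25 + np.cumsum(np.full((60, 2), 0.3), axis=0)
        still = np.tile(moving[-1], (15, 1))
        back = moving[-1] - np.cumsum(np.full((60, 2), 0.3), axis=0)
        traj = make_traj(np.vstack([moving, still, back]), dt=dt)
        eps = mm.segment_immobility(traj)
        assert eps.of_kind("immobile") == []

    def test_partition_property(self):
        traj = jittery_traj(7)
        eps = mm.segment_immobility(traj)
        total = eps.total_time("immobile") + eps.total_time("mobile")
        assert total == pytest.approx(traj.duration, abs=traj.dt)

    def test_min_dur_must_be_positive(self):
        with pytest.raises(ValueError):
            mm.segment_immobility(jittery_traj(1), min_dur=0.0)

    def test_lower_v_thresh_never_increases_immobile_time(self):
        traj = jittery_traj(11)
        hi = mm.segment_immobility(traj, v_thresh=2.0).total_time("immobile")
        lo = mm.segment_immobility(traj, v_thresh=0.5).total_time("immobile")
        assert lo <= hi + 1e-9

    def test_higher_min_dur_never_increases_count(self):
        traj = jittery_traj(13)
        short = len(mm.segment_immobility(traj, min_dur=2.0).of_kind("immobile"))
        long = len(mm.segment_immobility(traj, min_dur=5.0).of_kind("immobile"))
        assert long <= short

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        traj = jittery_traj(seed, n=600)
        eps = mm.segment_immobility(traj)
        expected = oracles.oracle_immobile_runs(
            traj.center, traj.dt, 2.0, 1.0, 0.5, 0.2
        )
        got = [
            (int(round(e.start / traj.dt)), int(round(e.end / traj.dt)))
            for e in eps.of_kind("immobile")
        ]
        assert got == expected


class TestFreezingSegmentation:
    def test_head_oscillation_blocks_freezing(self):
        # center still, head swinging 5 cm side to side: immobile, not frozen
        n, dt = 100, 0.1
        center = np.tile([25.0, 25.0], (n, 1))
        osc = 5.0 * np.sign(np.sin(np.arange(n)))
        head = center + np.column_stack([np.full(n, 2.0), osc])
        tail = center - [2.0, 0.0]
        traj = make_traj(center, head=head, tail=np.tile(tail[0], (n, 1)), dt=dt)
        imm = mm.segment_immobility(traj)
        assert imm.total_time("immobile") > 0
        frz = mm.segment_freezing(traj, imm)
        assert frz.total_time("freezing") == 0.0

    def test_fully_still_five_seconds(self):
        traj = stationary_traj(50, dt=0.1)  # 5 s, all three points fixed
        imm = mm.segment_immobility(traj)
        frz = mm.segment_freezing(traj, imm)
        eps = frz.of_kind("freezing")
        assert len(eps) == 1
        assert eps[0].duration == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_subset_property_on_simulated_sessions(self, seed, bp):
        meta = SessionMetadata(animal_id=f"s{seed}")
        traj = simulate_session(meta, None, bp, seed, dt=0.1, duration=120.0)
        imm = mm.segment_immobility(traj)
        frz = mm.segment_freezing(traj, imm)
        assert frz.total_time("freezing") <= imm.total_time("immobile") + 1e-9
        # frame-wise subset
        dt = traj.dt
        imm_mask = np.zeros(traj.n_frames, bool)
        for e in imm.of_kind("immobile"):
            imm_mask[int(round(e.start / dt)) : int(round(e.end / dt))] = True
        for e in frz.of_kind("freezing"):
            assert imm_mask[int(round(e.start / dt)) : int(round(e.end / dt))].all()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_oracle(self, seed, bp):
        meta = SessionMetadata(animal_id=f"f{seed}")
        traj = simulate_session(meta, None, bp, 100 + seed, dt=0.1, duration=60.0)
        imm = mm.segment_immobility(traj)
        frz = mm.segment_freezing(traj, imm)
        imm_runs = [
            (int(round(e.start / traj.dt)), int(round(e.end / traj.dt)))
            for e in imm.of_kind("immobile")
        ]
        expected = oracles.oracle_freezing_runs(
            traj.head, traj.tail, imm_runs, traj.n_frames, traj.dt, 2.0, 1.0, 0.5, 0.2
        )
        got = [
            (int(round(e.start / traj.dt)), int(round(e.end / traj.dt)))
            for e in frz.of_kind("freezing")
        ]
        assert got == expected


class TestMobileEpisodes:
    def test_fully_immobile_window_zero(self):
        traj = stationary_traj(200, dt=0.1)
        eps = mm.segment_immobility(traj)
        assert mm.mobile_episode_count(eps, (0.0, 20.0)) == 0

    def test_alternating_pattern_count(self):
        # 10 s mobile / 10 s immobile alternating for 5 minutes -> 15 onsets
        dt = 0.1
        blocks = []
        pos = np.array([5.0, 25.0])
        for k in range(15):
            direction = 0.3 if k % 2 == 0 else -0.3  # shuttle left-right
            walk = pos + np.cumsum(
                np.column_stack([np.full(100, direction), np.zeros(100)]), axis=0
            )
            blocks.append(walk)
            pos = walk[-1]
            blocks.append(np.tile(pos, (100, 1)))
        center = np.vstack(blocks)
        traj = make_traj(center, dt=dt)
        eps = mm.segment_immobility(traj)
        assert mm.mobile_episode_count(eps, (0.0, 300.0)) == 15

    def test_empty_window_errors(self):
        traj = stationary_traj(100)
        eps = mm.segment_immobility(traj)
        with pytest.raises(ValueError):
            mm.mobile_episode_count(eps, (5.0, 5.0))

    def test_recount_from_episode_list(self, bp):
        meta = SessionMetadata(animal_id="rc")
        traj = simulate_session(meta, None, bp, 77, dt=0.1, duration=300.0)
        eps = mm.segment_immobility(traj)
        window = (30.0, 250.0)
        manual = sum(
            1 for e in eps.of_kind("mobile") if window[0] <= e.start < window[1]
        )
        assert mm.mobile_episode_count(eps, window) == manual


def heading_traj(headings_rad, dt=0.1):
    n = len(headings_rad)
    center = np.tile([25.0, 25.0], (n, 1))
    offset = 2.0 * np.column_stack([np.cos(headings_rad), np.sin(headings_rad)])
    return make_traj(center, head=center + offset, tail=center - offset, dt=dt)


class TestRotations:
    def test_steady_ccw_two_turns(self):
        # heading advancing 4 degrees per frame through 720 degrees
        headings = np.deg2rad(np.arange(0, 721, 4))
        rot = mm.count_rotations(heading_traj(headings))
        assert (rot.cw, rot.ccw) == (0, 2)

    def test_steady_cw(self):
        headings = -np.deg2rad(np.arange(0, 361, 4))
        rot = mm.count_rotations(heading_traj(headings))
        assert (rot.cw, rot.ccw) == (1, 0)

    def test_oscillation_never_counts(self):
        headings = np.deg2rad(np.array([0.0, 179.0] * 50))
        rot = mm.count_rotations(heading_traj(headings))
        assert (rot.cw, rot.ccw) == (0, 0)

    def test_degenerate_frames_skipped(self):
        n = 50
        center = np.tile([25.0, 25.0], (n, 1))
        traj = make_traj(center, head=center + 0.2, tail=center)  # body < 1 cm
        rot = mm.count_rotations(traj)
        assert rot.skipped_frames == n
        assert rot.total == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_accumulator_oracle(self, seed):
        rng = np.random.default_rng(seed)
        headings = np.cumsum(rng.normal(0, 0.4, 800))
        rot = mm.count_rotations(heading_traj(headings))
        wrapped = np.rad2deg(np.arctan2(np.sin(headings), np.cos(headings)))
        cw, ccw = oracles.oracle_rotations(list(wrapped))
        assert (rot.cw, rot.ccw) == (cw, ccw)

    def test_time_reversal_swaps_directions(self):
        rng = np.random.default_rng(123)
        headings = np.cumsum(rng.normal(0.05, 0.3, 500))
        fwd = mm.count_rotations(heading_traj(headings))
        rev = mm.count_rotations(heading_traj(headings[::-1]))
        assert (fwd.cw, fwd.ccw) == (rev.ccw, rev.cw)

    def test_invariant_under_arena_rotation(self):
        rng = np.random.default_rng(5)
        headings = np.cumsum(rng.normal(0, 0.3, 400))
        base = mm.count_rotations(heading_traj(headings))
        rotated = mm.count_rotations(heading_traj(headings + np.pi / 2))
        assert (base.cw, base.ccw) == (rotated.cw, rotated.ccw)


class TestMaxSpeed:
    def test_jitter_filter_worked_example(self):
        # speeds 30, 120, 50 cm/s inside one bin -> bin max is 50
        dt = 0.1
        xs = np.concatenate([[5.0], 5.0 + np.cumsum([3.0, 12.0, 5.0])])
        center = np.column_stack([xs, np.full(4, 25.0)])
        traj = make_traj(center, dt=dt)
        bins = mm.max_speed_binned(traj)
        assert bins.values[0] == pytest.approx(50.0)

    def test_stationary_all_zero(self):
        traj = stationary_traj(400, dt=1.0)
        bins = mm.max_speed_binned(traj)
        assert np.all(bins.values[~bins.missing] == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_cap_property_simulated(self, seed, bp):
        meta = SessionMetadata(animal_id=f"cap{seed}")
        traj = simulate_session(meta, None, bp, seed, dt=0.05, duration=600.0)
        bins = mm.max_speed_binned(traj)
        assert np.all(bins.values[~bins.missing] <= 80.0 + 1e-9)

    def test_abs_and_avg(self):
        edges = np.arange(4) * 300.0
        bins = mm.BinSeries(
            "max_speed", edges, np.array([10.0, 20.0, 30.0]), np.zeros(3, bool)
        )
        absolute, averaged = mm.abs_and_avg_max_speed(bins, (0.0, 900.0))
        assert absolute == 30.0
        assert averaged == 20.0

    def test_constant_bins_equal(self):
        edges = np.arange(4) * 300.0
        bins = mm.BinSeries("max_speed", edges, np.full(3, 7.0), np.zeros(3, bool))
        absolute, averaged = mm.abs_and_avg_max_speed(bins, (0.0, 900.0))
        assert absolute == averaged == 7.0

    @settings(max_examples=40, deadline=None)
    @given(
        values=st.lists(
            st.floats(min_value=0, max_value=80, allow_nan=False),
            min_size=1,
            max_size=18,
        )
    )
    def test_avg_never_exceeds_abs(self, values):
        n = len(values)
        edges = np.arange(n + 1) * 300.0
        bins = mm.BinSeries("max_speed", edges, np.array(values), np.zeros(n, bool))
        absolute, averaged = mm.abs_and_avg_max_speed(bins, (0.0, n * 300.0))
        assert averaged <= absolute + 1e-12

    def test_unaligned_window_errors(self):
        edges = np.arange(4) * 300.0
        bins = mm.BinSeries("max_speed", edges, np.zeros(3), np.zeros(3, bool))
        with pytest.raises(ValueError):
            mm.abs_and_avg_max_speed(bins, (10.0, 700.0))


class TestDistance:
    def test_square_path(self):
        corners = np.array(
            [[10.0, 10.0], [20.0, 10.0], [20.0, 20.0], [10.0, 20.0], [10.0, 10.0]]
        )
        traj = make_traj(corners, dt=1.0)
        assert mm.distance_travelled(traj) == pytest.approx(40.0)

    def test_stationary_zero(self):
        assert mm.distance_travelled(stationary_traj(100)) == 0.0

    def test_circle_analytic(self):
        n_per_rev, revs, radius = 1000, 3, 10.0
        ang = 2 * np.pi * np.arange(n_per_rev * revs + 1) / n_per_rev
        center = np.column_stack([25 + radius * np.cos(ang), 25 + radius * np.sin(ang)])
        traj = make_traj(center, dt=0.05)
        expected = revs * 2 * np.pi * radius
        assert mm.distance_travelled(traj) == pytest.approx(expected, rel=1e-3)

    def test_jitter_steps_excluded(self):
        dt = 0.1
        xs = np.array([5.0, 6.0, 20.0, 21.0])  # middle step is 140 cm/s
        traj = make_traj(np.column_stack([xs, np.full(4, 25.0)]), dt=dt)
        assert mm.distance_travelled(traj) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_oracle(self, seed, bp):
        meta = SessionMetadata(animal_id=f"d{seed}")
        traj = simulate_session(meta, None, bp, seed, dt=0.1, duration=120.0)
        assert mm.distance_travelled(traj) == pytest.approx(
            oracles.oracle_distance(traj.center, traj.dt, 80.0), abs=1e-9
        )


class TestPctTime:
    def test_worked_example(self):
        eps = mm.EpisodeSet([mm.Episode(60.0, 90.0, "immobile")])
        assert mm.pct_time(eps, "immobile", (0.0, 300.0)) == pytest.approx(10.0)

    def test_no_episodes(self):
        assert mm.pct_time(mm.EpisodeSet([]), "freezing", (0.0, 100.0)) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_freezing_never_exceeds_immobile(self, seed, bp):
        meta = SessionMetadata(animal_id=f"p{seed}")
        traj = simulate_session(meta, None, bp, seed, dt=0.1, duration=200.0)
        eps = mm.segment_all(traj)
        w = (0.0, 200.0)
        assert mm.pct_time(eps, "freezing", w) <= mm.pct_time(eps, "immobile", w) + 1e-9


class TestTOISummary:
    def test_spans_ten_bins(self):
        starts = np.arange(600.0, 3600.0, 300.0)
        assert len(starts) == 10

    def test_all_zero_trajectory(self):
        traj = stationary_traj(5400, dt=1.0)
        summary = mm.toi_summary(traj)
        assert summary.distance_cm == 0.0
        assert summary.mobile_episode_count == 0
        assert summary.pct_time_immobile == pytest.approx(100.0)
        assert summary.pct_time_freezing == pytest.approx(100.0)

    def test_truncated_session_errors_listing_bins(self, bp):
        meta = SessionMetadata(animal_id="tr")
        traj = simulate_session(meta, None, bp, 4, dt=0.5, duration=1800.0)
        with pytest.raises(Exception, match="missing bins"):
            mm.toi_summary(traj)

    def test_consistent_with_bin_series(self, bp):
        meta = SessionMetadata(animal_id="cons")
        traj = simulate_session(meta, None, bp, 21, dt=0.2, duration=3600.0)
        episodes = mm.segment_all(traj)
        summary = mm.toi_summary(traj, episodes=episodes)
        series = mm.all_bin_series(traj, episodes=episodes)
        toi = (600.0, 3600.0)
        assert summary.distance_cm == pytest.approx(
            np.sum(series["distance"].window_values(toi)), rel=1e-9
        )
        assert summary.mobile_episode_count == int(
            np.sum(series["mobile_episodes"].window_values(toi))
        )
        assert summary.pct_time_immobile == pytest.approx(
            np.mean(series["pct_immobile"].window_values(toi)), rel=1e-9
        )
        assert summary.avg_max_speed <= summary.abs_max_speed + 1e-12
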