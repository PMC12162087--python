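"""Stimulus construction: schedules, dot kinematics, disparity, apertures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fstloc import stimuli


class TestSchedules:
    @pytest.mark.parametrize(
        "block_s,reps,n_blocks,stim_s",
        [(15, 3, 24, 360), (15, 1, 8, 120), (10, 2, 16, 160)],
    )
    def test_2d_block_arithmetic(self, block_s, reps, n_blocks, stim_s):
        s = stimuli.build_2d_schedule(block_s, reps)
        assert len(s.blocks) == n_blocks + 1  # + final blank
        assert s.blocks[-1].label == "blank"
        assert s.total_duration - s.blocks[-1].duration == stim_s
        # moving/static strictly alternate, each direction `reps` times
        labels = s.labels()[:-1]
        assert labels[1::2] == ["static"] * (n_blocks // 2)
        for d in stimuli.MOTION_2D_LABELS:
            assert labels.count(d) == reps

    @pytest.mark.parametrize(
        "block_s,reps,n_blocks,stim_s", [(10, 15, 30, 300), (10, 1, 2, 20), (5, 4, 8, 40)]
    )
    def test_3d_block_arithmetic(self, block_s, reps, n_blocks, stim_s):
        s = stimuli.build_3d_schedule(block_s, reps)
        assert len(s.blocks) == n_blocks + 1
        assert s.total_duration - s.blocks[-1].duration == stim_s
        labels = s.labels()[:-1]
        assert labels == ["coherent", "scrambled"] * reps

    @pytest.mark.parametrize("block_s,n,total", [(15, 21, 315), (15, 2, 30), (10, 5, 50)])
    def test_opponent_block_arithmetic(self, block_s, n, total):
        s = stimuli.build_opponent_schedule(block_s, n)
        assert s.total_duration == total
        labels = s.labels()
        assert labels[0] == "unpaired"
        assert all(a != b for a, b in zip(labels, labels[1:]))

    @pytest.mark.parametrize("bad", [(-1, 3), (0, 3), (15, 0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            stimuli.build_2d_schedule(*bad)
        with pytest.raises(ValueError):
            stimuli.build_3d_schedule(*bad)

    @given(
        block_s=st.integers(min_value=1, max_value=30),
        reps=st.integers(min_value=1, max_value=5),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_durations_match_closed_form(self, block_s, reps):
        s2 = stimuli.build_2d_schedule(block_s, reps)
        assert s2.total_duration == 4 * reps * 2 * block_s + 15
        s3 = stimuli.build_3d_schedule(block_s, reps)
        assert s3.total_duration == 2 * reps * block_s + 15
        for s in (s2, s3):
            ends = [b.onset + b.duration for b in s.blocks]
            assert all(
                b.onset >= e - 1e-9 for b, e in zip(s.blocks[1:], ends)
            )  # non-overlap

    def test_events_roundtrip(self, tmp_path):
        from fstloc import io

        s = stimuli.build_3d_schedule(10, 2)
        io.write_events(s, tmp_path / "ev.tsv")
        back = io.read_events(tmp_path / "ev.tsv")
        assert back.labels() == s.labels()
        assert back.total_duration == s.total_duration


@pytest.fixture(scope="module")
def movie():
    sched = stimuli.build_2d_schedule(5, 1, blank_s=5)
    return stimuli.gen_2d_dot_movie(sched, seed=11, frame_rate=60)


class TestDotMovie2D:
    def test_dots_stay_in_aperture_within_lifetime(self, movie):
        assert movie.eccentricity().max() <= movie.aperture_radius + 1e-6
        assert movie.age.max() < movie.lifetime

    def test_speed_bounded_by_maximum(self, movie):
        speeds = movie.speeds()
        assert np.nanmax(speeds) <= 12.0 + 1e-6

    def test_radial_speed_follows_sqrt_scaling(self, movie):
        # dot at ecc 2.5 in a radial block moves at 12*sqrt(2.5/10) = 6 deg/s
        labels = np.asarray(movie.frame_labels)
        frames = np.flatnonzero(np.isin(labels[:-1], ["radial_in", "radial_out"]))
        ecc = movie.eccentricity()[frames]
        v = movie.speeds()[frames]
        ok = np.isfinite(v) & (ecc > 0.1)
        expected = 12.0 * np.sqrt(ecc[ok] / 10.0)
        step_err = 12.0 / 60.0  # one frame-step discretization bound
        assert np.max(np.abs(v[ok] - expected)) < step_err
        near = ok & (np.abs(ecc - 2.5) < 0.01)
        if near.sum():
            assert np.allclose(v[near], 6.0, atol=0.1)

    def test_static_blocks_freeze_positions(self, movie):
        labels = np.asarray(movie.frame_labels)
        frames = np.flatnonzero(labels[:-1] == "static")
        v = movie.speeds()[frames]
        assert np.nanmax(v) == 0.0

    def test_deterministic_given_seed(self):
        sched = stimuli.build_2d_schedule(2, 1, blank_s=2)
        a = stimuli.gen_2d_dot_movie(sched, seed=3, frame_rate=30)
        b = stimuli.gen_2d_dot_movie(sched, seed=3, frame_rate=30)
        assert np.array_equal(a.xy, b.xy)

    def test_unknown_label_rejected(self):
        sched = stimuli.BlockSchedule(
            [stimuli.Block("warp", 0.0, 5.0)], total_duration=5.0
        )
        with pytest.raises(ValueError, match="warp"):
            stimuli.gen_2d_dot_movie(sched, seed=0)


@pytest.fixture(scope="module")
def paired():
    return stimuli.gen_opponent_movie("paired", 1.0, seed=2)


@pytest.fixture(scope="module")
def unpaired():
    return stimuli.gen_opponent_movie("unpaired", 1.0, seed=2)


class TestOpponentMovie:
    def test_exactly_300_dots_every_frame(self, paired, unpaired):
        for m in (paired, unpaired):
            assert m.xy.shape[1] == 300
            assert np.all(np.isfinite(m.xy))

    def test_pair_lifetime_is_point_one_second(self, paired):
        # 0.5 deg closing at 2 * 5 deg/s relative speed
        assert paired.lifetime == pytest.approx(0.1)
        assert paired.age.max() < 0.1

    def test_pair_members_share_y_and_stay_close(self, paired):
        y_diff = paired.xy[:, 0::2, 1] - paired.xy[:, 1::2, 1]
        assert np.abs(y_diff).max() == 0.0
        sep = np.abs(paired.xy[:, 0::2, 0] - paired.xy[:, 1::2, 0])
        assert sep.max() <= 0.5 + 1e-5

    def test_constant_speed_five(self, paired, unpaired):
        for m in (paired, unpaired):
            v = m.speeds()
            assert np.allclose(v[np.isfinite(v)], 5.0, atol=1e-3)

    def test_direction_histogram_matches_between_conditions(self, paired, unpaired):
        for m in (paired, unpaired):
            dx = np.diff(m.xy[..., 0], axis=0)
            valid = np.isfinite(m.speeds())
            rightward = (dx > 0) & valid
            leftward = (dx < 0) & valid
            # every frame transition: 150 dots each way (minus respawns)
            assert np.all(rightward.sum(axis=1) <= 150)
            assert np.all(leftward.sum(axis=1) <= 150)
            assert rightward.sum() > 0 and leftward.sum() > 0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            stimuli.gen_opponent_movie("antiphase", 1.0, seed=0)


class TestDisparity:
    def test_antiphase_and_amplitude(self):
        d = stimuli.gen_disparity_trajectory("coherent", 120, 4.0, 0)
        assert np.abs(d.center_disparity + d.surround_disparity).max() == 0.0
        assert np.abs(d.center_disparity).max() == pytest.approx(18.0)

    def test_scramble_preserves_multiset_and_differs(self):
        coh = stimuli.gen_disparity_trajectory("coherent", 120, 2.0, 0)
        scr = stimuli.gen_disparity_trajectory("scrambled", 120, 2.0, 0)
        assert np.allclose(
            np.sort(coh.center_disparity), np.sort(scr.center_disparity)
        )
        assert not np.array_equal(coh.center_disparity, scr.center_disparity)

    @given(seed=st.integers(min_value=0, max_value=50))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_scramble_is_bijection_per_second(self, seed):
        coh = stimuli.gen_disparity_trajectory("coherent", 60, 2.0, seed)
        scr = stimuli.gen_disparity_trajectory("scrambled", 60, 2.0, seed)
        # every 1 s window contains the same disparity levels in both
        for s0 in range(0, coh.n_frames, 60):
            a = np.sort(coh.center_disparity[s0 : s0 + 60])
            b = np.sort(scr.center_disparity[s0 : s0 + 60])
            assert np.allclose(a, b)

    def test_non_cycle_duration_rejected(self):
        with pytest.raises(ValueError):
            stimuli.gen_disparity_trajectory("coherent", 120, 3.0, 0)


class TestApertures:
    def test_bar_sweep_union_covers_field(self):
        ap = stimuli.gen_prf_apertures("bar", radius=12.2, grid_size=64, n_steps=8)
        union = ap.grid.any(axis=0)
        field = ap.field_mask()
        assert union[field].mean() >= 0.95

    def test_full_field_ring_equals_field(self):
        ap = stimuli.gen_prf_apertures(
            "ring", radius=12.2, grid_size=64, n_steps=4, ring_rel_width=1.0
        )
        assert np.array_equal(ap.grid[0], ap.field_mask())

    def test_masks_subset_of_circular_field(self):
        for kind in ("bar", "wedge", "ring"):
            ap = stimuli.gen_prf_apertures(kind, radius=10, grid_size=40, n_steps=4)
            outside = ~ap.field_mask()
            assert not ap.grid[:, outside].any()
            areas = ap.area()
            assert np.all(areas >= 0) and np.all(areas <= np.pi * 10**2)

    def test_edge_bar_positions_clipped_by_circular_field(self):
        ap = stimuli.gen_prf_apertures(
            "bar", radius=12.2, grid_size=64, n_steps=8, directions=(0.0,), step_trs=1
        )
        areas = ap.area()
        assert areas[0] < areas[4]  # edge strips lose area to the field circle
        assert areas[-1] < areas[3]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            stimuli.gen_prf_apertures("spiral")
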