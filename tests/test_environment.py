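"""Stimulus world: glyphs, trajectories, rendering, noise, catcher goals."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstnet.environment import (
    GLYPHS,
    OPPOSITE_TRAJECTORY,
    RETINA_SHAPE,
    TRAJECTORIES,
    SINGLE_OBJECT_MIX,
    TWO_OBJECT_MIX,
    StimulusTrial,
    expected_response,
    inject_noise,
    make_trial,
    render_frame,
)


class TestGlyphs:
    def test_three_distinct_letters(self):
        bitmaps = [GLYPHS[k].bitmap for k in "TLJ"]
        assert len(bitmaps) == 3
        for i in range(3):
            for j in range(i + 1, 3):
                assert not np.array_equal(bitmaps[i], bitmaps[j])

    def test_glyphs_fit_with_room_to_traverse(self):
        for g in GLYPHS.values():
            assert g.bitmap.shape[0] < RETINA_SHAPE[0]
            assert g.bitmap.shape[1] < RETINA_SHAPE[1]

    def test_glyphs_visible_to_presence_detectors(self):
        # the motion-stream presence threshold needs >= 7 pixels in a 4x4 RF
        for g in GLYPHS.values():
            assert g.bitmap.sum() >= 7


class TestTrajectories:
    def test_eight_unique_corner_direction_pairs(self):
        combos = {(t.start_corner, t.direction) for t in TRAJECTORIES}
        assert len(combos) == 8

    def test_opposite_is_an_involution_with_same_direction(self):
        for idx, opp in OPPOSITE_TRAJECTORY.items():
            assert OPPOSITE_TRAJECTORY[opp] == idx
            assert TRAJECTORIES[idx].direction == TRAJECTORIES[opp].direction
            assert idx != opp

    def test_arrival_corners_bijective_per_direction(self):
        for direction in ("lateral", "vertical"):
            arr = [t.arrival_corner for t in TRAJECTORIES if t.direction == direction]
            assert sorted(arr) == sorted(["UL", "UR", "LL", "LR"])

    @pytest.mark.parametrize("traj", range(8))
    def test_object_exits_in_finite_time(self, traj):
        trial = StimulusTrial([("T", traj)])
        assert render_frame(trial, trial.duration).sum() == 0


class TestRenderFrame:
    def test_anchored_at_start_corner(self):
        trial = StimulusTrial([("T", 0)])  # UL lateral
        frame = render_frame(trial, 0)
        g = GLYPHS["T"].bitmap
        assert np.array_equal(frame[: g.shape[0], : g.shape[1]], g)

    def test_advances_one_pixel_per_speed_period(self):
        trial = StimulusTrial([("T", 0)], speed=10)
        f0, f9, f10 = (render_frame(trial, t) for t in (0, 9, 10))
        assert np.array_equal(f0, f9)          # still dwelling
        assert np.array_equal(f10[:, 1:], f0[:, :-1])  # shifted right by 1

    def test_two_objects_are_ored(self):
        trial = StimulusTrial([("T", 0), ("L", 4)])
        merged = render_frame(trial, 0)
        t_only = render_frame(StimulusTrial([("T", 0)]), 0)
        l_only = render_frame(StimulusTrial([("L", 4)]), 0)
        assert np.array_equal(merged, t_only | l_only)

    def test_pixel_budget(self):
        # a noiseless frame never exceeds objects x glyph-on-pixels
        trial = StimulusTrial([("T", 0), ("J", 5)])
        budget = GLYPHS["T"].bitmap.sum() + GLYPHS["J"].bitmap.sum()
        for t in range(0, trial.duration, 7):
            assert render_frame(trial, t).sum() <= budget


class TestNoise:
    def test_p_zero_identity(self):
        frame = render_frame(StimulusTrial([("L", 2)]), 0)
        rng = np.random.default_rng(0)
        assert np.array_equal(inject_noise(frame, 0.0, rng), frame)

    def test_p_one_complement(self):
        frame = render_frame(StimulusTrial([("L", 2)]), 0)
        rng = np.random.default_rng(0)
        assert np.array_equal(inject_noise(frame, 1.0, rng), ~frame)

    def test_mean_flip_count(self):
        # 8% noise flips on average 8 of 100 pixels
        frame = np.zeros(RETINA_SHAPE, dtype=bool)
        rng = np.random.default_rng(1)
        flips = [int(inject_noise(frame, 0.08, rng).sum()) for _ in range(800)]
        assert np.mean(flips) == pytest.approx(8.0, abs=0.35)

    def test_preserves_shape_and_binarity(self):
        frame = render_frame(StimulusTrial([("J", 7)]), 30)
        out = inject_noise(frame, 0.3, np.random.default_rng(2))
        assert out.shape == frame.shape and out.dtype == bool

    def test_flip_independence_chi_square(self):
        # each pixel's flip count over many draws is ~Binomial(n, p)
        from scipy import stats

        rng = np.random.default_rng(3)
        frame = np.zeros(RETINA_SHAPE, dtype=bool)
        n = 500
        counts = np.zeros(RETINA_SHAPE)
        for _ in range(n):
            counts += inject_noise(frame, 0.2, rng)
        _, p = stats.chisquare(counts.ravel())
        assert p > 0.001  # no pixel is systematically favoured


class TestMakeTrial:
    def test_single_object_mix_uniform(self):
        rng = np.random.default_rng(0)
        letters, corners = [], []
        for _ in range(3000):
            trial = make_trial(rng, SINGLE_OBJECT_MIX)
            assert len(trial.objects) == 1
            letters.append(trial.objects[0][0])
            corners.append(TRAJECTORIES[trial.objects[0][1]].start_corner)
        for letter in "TLJ":
            assert letters.count(letter) / 3000 == pytest.approx(1 / 3, abs=0.04)
        for corner in ("UL", "UR", "LL", "LR"):
            assert corners.count(corner) / 3000 == pytest.approx(1 / 4, abs=0.04)

    def test_two_object_mix_proportions(self):
        rng = np.random.default_rng(1)
        tally = {"T": 0, "L": 0, "TL": 0}
        n = 10_000
        for _ in range(n):
            trial = make_trial(rng, TWO_OBJECT_MIX)
            key = "".join(sorted(trial.letters, reverse=True))
            tally[key] += 1
        assert tally["T"] / n == pytest.approx(0.25, abs=0.02)
        assert tally["L"] / n == pytest.approx(0.25, abs=0.02)
        assert tally["TL"] / n == pytest.approx(0.50, abs=0.02)

    def test_seeded_reproducibility(self):
        t1 = [make_trial(np.random.default_rng(7), TWO_OBJECT_MIX) for _ in range(5)]
        t2 = [make_trial(np.random.default_rng(7), TWO_OBJECT_MIX) for _ in range(5)]
        assert [t.objects for t in t1] == [t.objects for t in t2]

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            make_trial(np.random.default_rng(0), {("T",): 0.6, ("L",): 0.6})


class TestExpectedResponse:
    def test_target_caught_at_its_own_arrival(self):
        # T moving UL -> UR is caught at the upper-right arrival placement
        trial = StimulusTrial([("T", 0)])
        assert expected_response(trial).expected_motor_index == 0

    def test_avoidance_goes_diagonally_opposite(self):
        # L arriving upper-right -> catcher at the lower-left placement,
        # i.e. the arrival of the reverse bottom-edge trajectory
        trial = StimulusTrial([("L", 0)])
        goal = expected_response(trial).expected_motor_index
        assert TRAJECTORIES[goal].arrival_corner == "LL"
        assert TRAJECTORIES[goal].direction == "lateral"

    def test_distractor_alone_expects_silence(self):
        assert expected_response(StimulusTrial([("J", 3)])).expected_motor_index is None

    def test_target_takes_priority_over_avoidance(self):
        trial = StimulusTrial([("T", 2), ("L", 5)])
        assert expected_response(trial).expected_motor_index == 2

    @given(st.integers(0, 7))
    @settings(max_examples=8, deadline=None)
    def test_trajectory_anchor_stays_on_its_edge(self, traj_idx):
        trial = StimulusTrial([("T", traj_idx)])
        traj = TRAJECTORIES[traj_idx]
        for t in range(0, trial.duration, 10):
            frame = render_frame(trial, t)
            if not frame.any():
                continue
            rows, cols = np.nonzero(frame)
            if traj.direction == "lateral":
                edge_row = 0 if traj.start_corner[0] == "U" else 6
                assert rows.min() >= edge_row and rows.max() < edge_row + 4
            else:
                edge_col = 0 if traj.start_corner[1] == "L" else 6
                assert cols.min() >= edge_col and cols.max() < edge_col + 4
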