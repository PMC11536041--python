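"""Kymograph extraction and run/pause/passive segmentation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acdkit.core import PixelCalibration
from acdkit.kymo import (
    CARGO_PARAMS,
    EB3_PARAMS,
    MotilityParams,
    TrajectoryTrace,
    analyze_trajectory,
    classify_direction,
    extract_kymograph,
    segment_trajectory,
    summarize_motility,
)
from acdkit.synthetic import make_kymograph

from oracles import oracle_segment_states, states_from_segments


def trace_from_moves(moves, cal, start=0.0):
    pos = np.concatenate([[start], start + np.cumsum(moves)])
    return TrajectoryTrace(np.arange(len(pos)), pos, cal)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

class TestExtractKymograph:
    def test_static_spot_gives_constant_bright_column(self, live_cal):
        stack = np.zeros((6, 40, 60))
        stack[:, 20, 25] = 10.0
        path = np.array([[5.0, 20.0], [55.0, 20.0]])
        kg = extract_kymograph(stack, path, live_cal, width_px=1)
        assert kg.matrix.shape[0] == 6
        assert np.all(np.argmax(kg.matrix, axis=1) == 20)  # arc position 25-5

    def test_moving_spot_traces_unit_slope_diagonal(self, live_cal):
        stack = np.zeros((10, 30, 60))
        for t in range(10):
            stack[t, 15, 10 + t] = 5.0
        path = np.array([[5.0, 15.0], [50.0, 15.0]])
        kg = extract_kymograph(stack, path, live_cal, width_px=3)
        ridge = np.argmax(kg.matrix, axis=1)
        assert np.all(np.diff(ridge) == 1)

    def test_width_irrelevant_on_uniform_image(self, live_cal):
        stack = np.full((3, 30, 30), 7.0)
        path = np.array([[5.0, 15.0], [25.0, 15.0]])
        k1 = extract_kymograph(stack, path, live_cal, width_px=1)
        k3 = extract_kymograph(stack, path, live_cal, width_px=3)
        np.testing.assert_allclose(k1.matrix, k3.matrix)

    def test_path_outside_image_rejected(self, live_cal):
        stack = np.zeros((2, 10, 10))
        with pytest.raises(ValueError, match="exits"):
            extract_kymograph(stack, np.array([[0.0, 5.0], [50.0, 5.0]]), live_cal)


# ---------------------------------------------------------------------------
# segmentation rules
# ---------------------------------------------------------------------------

class TestSegmentationRules:
    def test_all_positions_equal_is_single_pause_not_mobile(self, live_cal):
        tr = TrajectoryTrace(np.arange(20), np.full(20, 7.0), live_cal)
        segs, mobile = segment_trajectory(tr)
        assert [s.kind for s in segs] == ["pause"]
        assert not mobile

    def test_ten_frame_unit_run_is_mobile(self, live_cal):
        tr = trace_from_moves([1.0] * 10, live_cal)
        segs, mobile = segment_trajectory(tr)
        assert mobile
        (run,) = segs
        assert run.kind == "run" and run.displacement_px == 10.0

    def test_alternating_move_stop_pattern_is_passive(self, live_cal):
        """Move 1 px, stop 1 frame, repeat: neither stationary nor a run."""
        tr = trace_from_moves([1.0, 0.0] * 6, live_cal)
        segs, mobile = segment_trajectory(tr)
        assert not mobile
        assert {s.kind for s in segs} == {"passive"}

    def test_four_frame_move_fails_five_frame_minimum(self, live_cal):
        tr = trace_from_moves([1.0] * 4 + [0.0] * 6, live_cal)
        _, mobile = segment_trajectory(tr)
        assert not mobile

    def test_single_zero_frame_absorbed_into_run(self, live_cal):
        tr = trace_from_moves([1.0, 1.0, 1.0, 0.0, 1.0, 1.0], live_cal)
        segs, mobile = segment_trajectory(tr)
        assert mobile
        (run,) = segs
        assert run.displacement_px == 5.0
        assert run.frame_end - run.frame_start == 6

    def test_run_and_interleaved_pause(self, live_cal):
        tr = trace_from_moves([1.0] * 6 + [0.0] * 4 + [1.0] * 6, live_cal)
        segs, _ = segment_trajectory(tr)
        assert [s.kind for s in segs] == ["run", "pause", "run"]
        net = sum(s.displacement_px for s in segs)
        assert net == 12.0

    def test_non_monotone_frames_rejected(self, live_cal):
        with pytest.raises(ValueError, match="strictly increasing"):
            TrajectoryTrace(np.array([0, 2, 1]), np.zeros(3), live_cal)

    def test_eb3_long_stall_terminates_comet(self, eb3_cal):
        moves = [1.0] * 5 + [0.0] * 12 + [1.0] * 5
        tr = trace_from_moves(moves, eb3_cal)
        segs, mobile = segment_trajectory(tr, EB3_PARAMS)
        assert mobile
        assert all(s.frame_end <= 5 for s in segs)  # nothing after the stall

    def test_eb3_two_pixel_run_qualifies(self, eb3_cal):
        tr = trace_from_moves([1.0, 1.0, 0.0, 0.0], eb3_cal)
        segs, mobile = segment_trajectory(tr, EB3_PARAMS)
        assert mobile
        assert segs[0].kind == "run" and segs[0].displacement_px == 2.0

    def test_eb3_has_no_passive_class(self, eb3_cal):
        tr = trace_from_moves([1.0, 0.0] * 4, eb3_cal)
        segs, _ = segment_trajectory(tr, EB3_PARAMS)
        assert all(s.kind != "passive" for s in segs)


# ---------------------------------------------------------------------------
# oracle equivalence and properties
# ---------------------------------------------------------------------------

@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.lists(st.sampled_from([-2.0, -1.0, 0.0, 1.0, 2.0]), min_size=1, max_size=40),
    st.sampled_from(["cargo", "eb3"]),
)
def test_segmentation_matches_window_enumeration_oracle(moves, preset):
    cal = PixelCalibration(0.13, 0.2)
    params = EB3_PARAMS if preset == "eb3" else CARGO_PARAMS
    tr = trace_from_moves(moves, cal)
    segs, _ = segment_trajectory(tr, params)
    expected = oracle_segment_states(moves, params)
    got = states_from_segments(segs, len(expected))
    assert got == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([-3.0, -1.0, 0.0, 1.0, 3.0]), min_size=1, max_size=30))
def test_time_fractions_partition_to_one(moves):
    cal = PixelCalibration(0.13, 0.2)
    tr = trace_from_moves(moves, cal)
    s = analyze_trajectory(tr)
    total = (
        s.fraction_time_running
        + s.fraction_time_pausing
        + s.fraction_time_passive
        + s.fraction_time_unclassified
    )
    assert total == pytest.approx(1.0)
    assert s.fraction_time_unclassified >= -1e-12


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([-2.0, -1.0, 0.0, 1.0, 2.0]), min_size=2, max_size=30))
def test_reversal_count_invariant_under_time_reversal_with_negation(moves):
    cal = PixelCalibration(0.13, 0.2)
    fwd = analyze_trajectory(trace_from_moves(moves, cal))
    # reversing time and negating position preserves each displacement
    # in order-reversed sequence; reversals must not change
    rev_moves = list(reversed(moves))
    rev = analyze_trajectory(trace_from_moves(rev_moves, cal))
    assert fwd.n_direction_changes == rev.n_direction_changes


def test_net_displacement_equals_sum_of_per_frame_moves(live_cal, rng):
    moves = rng.integers(-3, 4, size=50).astype(float)
    tr = trace_from_moves(moves, live_cal)
    s = analyze_trajectory(tr)
    assert s.net_displacement_px == pytest.approx(moves.sum())
    segs, _ = segment_trajectory(tr)
    seg_disp = sum(x.displacement_px for x in segs)
    state = states_from_segments(segs, len(moves))
    unclassified_disp = sum(m for m, st_ in zip(moves, state) if st_ == "unclassified")
    assert seg_disp + unclassified_disp == pytest.approx(moves.sum())


def test_doubling_frame_interval_halves_velocities():
    moves = [2.0] * 8
    v1 = analyze_trajectory(
        trace_from_moves(moves, PixelCalibration(0.13, 0.2))
    ).runs[0].velocity_um_s
    v2 = analyze_trajectory(
        trace_from_moves(moves, PixelCalibration(0.13, 0.4))
    ).runs[0].velocity_um_s
    assert v1 == pytest.approx(2 * v2)


# ---------------------------------------------------------------------------
# direction and summaries
# ---------------------------------------------------------------------------

class TestDirection:
    def test_two_runs_with_reversal(self, live_cal):
        tr = trace_from_moves([2.0] * 5 + [-1.0] * 3, live_cal)
        params = MotilityParams(run_min_px=3, run_min_frames=3)
        segs, _ = segment_trajectory(tr, params)
        s = classify_direction(segs, tr, params)
        assert s.net_displacement_px == pytest.approx(7.0)
        assert s.direction == "anterograde"
        assert s.n_direction_changes == 1

    def test_single_retrograde_run(self, live_cal):
        tr = trace_from_moves([-1.0] * 8, live_cal)
        s = analyze_trajectory(tr)
        assert s.direction == "retrograde"

    def test_stationary_track_has_no_direction(self, live_cal):
        tr = TrajectoryTrace(np.arange(10), np.full(10, 3.0), live_cal)
        s = analyze_trajectory(tr)
        assert s.direction == "none" and not s.mobile


class TestSummaries:
    def test_all_stationary_region(self, live_cal):
        tracks = [
            TrajectoryTrace(np.arange(15), np.full(15, i * 3.0), live_cal)
            for i in range(4)
        ]
        df = summarize_motility({"AIS": tracks})
        row = df.iloc[0]
        assert row["pct_mobile"] == 0.0
        assert row["pct_stationary"] == 100.0
        assert np.isnan(row["pct_anterograde"])  # absent, not zero

    def test_known_run_schedule_recovers_length_and_velocity(self):
        # 2 µm anterograde runs at 1 µm/s: 0.13 µm/px, 0.13 s/frame, 1 px/frame
        cal = PixelCalibration(0.13, 0.13)
        moves = [1.0] * 15 + [0.0] * 4  # 15 px = 1.95 um run
        tracks = [trace_from_moves(moves, cal) for _ in range(10)]
        df = summarize_motility({"axon": tracks})
        row = df.iloc[0]
        assert row["pct_mobile"] == 100.0
        assert row["mean_run_length_um_antero"] == pytest.approx(1.95)
        assert row["mean_run_velocity_um_s_antero"] == pytest.approx(1.0)

    def test_planted_time_fractions_recovered(self, live_cal):
        moves = [1.0] * 14 + [0.0] * 4 + [1.0, 0.0] * 1  # 14 run, 4 pause, 2 leftover
        tr = trace_from_moves(moves, live_cal)
        s = analyze_trajectory(tr)
        assert s.fraction_time_running == pytest.approx(14 / 20, abs=1 / 20)
        assert s.fraction_time_pausing == pytest.approx(4 / 20, abs=1 / 20)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="no tracks"):
            summarize_motility({"AIS": []})

    def test_eb3_comet_density_per_um_minute(self, eb3_cal):
        moves = [1.0] * 6
        tracks = [trace_from_moves(moves, eb3_cal) for _ in range(12)]
        df = summarize_motility(
            {"axon": tracks},
            EB3_PARAMS,
            region_path_length_um={"axon": 20.0},
            region_recording_min={"axon": 3.0},
        )
        assert df.iloc[0]["comet_density_per_um_min"] == pytest.approx(12 / 60.0)
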