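"""The nine motion metrics and the two-stage normalization."""

import warnings

import numpy as np
import pandas as pd
import pytest

from surgtrack.indicators import IndicatorState
from surgtrack.metrics import (
    METRIC_NAMES,
    MetricNormalizer,
    average_speed,
    count_collisions,
    count_instrument_changes,
    count_movements,
    count_out_of_view,
    economic_factor,
    economy_of_motion,
    laparoscopy_usage,
    movement_episodes,
    normalize_metrics,
)


def traj(x, y, valid=None, visible=None, frame0=0):
    n = len(x)
    return pd.DataFrame(
        {
            "frame": np.arange(frame0, frame0 + n),
            "x_mm": np.asarray(x, float),
            "y_mm": np.asarray(y, float),
            "visible": np.ones(n, bool) if visible is None else visible,
            "valid_motion": np.ones(n, bool) if valid is None else valid,
        }
    )


def states(n, cam=(), arms=frozenset({"left", "right"})):
    return [IndicatorState(f, f in cam, arms) for f in range(n)]


# -- economy of motion -----------------------------------------------------


def test_economy_stationary_is_zero():
    t = traj(np.full(50, 3.0), np.full(50, 4.0))
    assert economy_of_motion({0: t}) == 0.0


@pytest.mark.parametrize("n", [2, 11, 101])
def test_economy_straight_segment_is_fifty(n):
    x = np.linspace(0, 30, n)
    y = np.linspace(0, 40, n)
    assert economy_of_motion({0: traj(x, y)}) == pytest.approx(50.0)


def test_economy_circle_approaches_circumference():
    th = np.linspace(0, 2 * np.pi, 1001)
    t = traj(10 * np.cos(th), 10 * np.sin(th))
    assert economy_of_motion({0: t}) == pytest.approx(2 * np.pi * 10, abs=0.1)


def test_economy_invalid_steps_excluded():
    x = np.arange(10, dtype=float)
    valid = np.ones(10, bool)
    valid[4:7] = False
    got = economy_of_motion({0: traj(x, np.zeros(10), valid=valid)})
    # steps 0-3 (3 units) and 7-9 (2 units); the 3-4 and 6-7 edges are cut too
    assert got == pytest.approx(5.0)


def test_economy_time_reversal_invariant():
    rng = np.random.default_rng(0)
    x, y = rng.random(50) * 30, rng.random(50) * 30
    fwd = economy_of_motion({0: traj(x, y)})
    rev = economy_of_motion({0: traj(x[::-1], y[::-1])})
    assert fwd == pytest.approx(rev)


def test_economy_resampling_insensitive_within_two_percent():
    th_hi = np.linspace(0, 2 * np.pi, 2001)
    th_lo = np.linspace(0, 2 * np.pi, 201)
    hi = economy_of_motion({0: traj(12 * np.cos(th_hi), 12 * np.sin(th_hi))})
    lo = economy_of_motion({0: traj(12 * np.cos(th_lo), 12 * np.sin(th_lo))})
    assert abs(hi - lo) / hi < 0.02


# -- average speed ---------------------------------------------------------


def test_average_speed_constant_glide():
    """A 50 mm straight glide over 10 s at fps 10 -> 5 mm/s."""
    n = 101
    x = np.linspace(0, 50, n)
    assert average_speed({0: traj(x, np.zeros(n))}, fps=10) == pytest.approx(
        5.0, rel=0.02
    )


def test_average_speed_ignores_pauses():
    x = np.concatenate([np.linspace(0, 50, 101), np.full(100, 50.0)])
    got = average_speed({0: traj(x, np.zeros(201))}, fps=10)
    assert got == pytest.approx(5.0, rel=0.1)


def test_average_speed_zero_when_all_motion_gated():
    x = np.linspace(0, 50, 101)
    valid = np.zeros(101, bool)
    assert average_speed({0: traj(x, np.zeros(101), valid=valid)}, fps=10) == 0.0


def test_average_speed_requires_fps_and_data():
    with pytest.raises(ValueError):
        average_speed({0: traj([0, 1], [0, 0])}, fps=0)
    with pytest.raises(ValueError):
        average_speed({0: traj([], [])}, fps=10)


def test_average_speed_recovers_simulator_speed():
    """Constant 4 mm/s in the generator comes back as 4 mm/s."""
    fps = 20.0
    n = 400
    x = np.arange(n) * 4.0 / fps
    assert average_speed({0: traj(x, np.zeros(n))}, fps=fps) == pytest.approx(
        4.0, abs=0.1
    )


# -- out of view -----------------------------------------------------------


def test_out_of_view_counts():
    n = 100
    st = states(n)
    arm_of = {0: "left"}
    always = traj(np.zeros(n), np.zeros(n))
    assert count_out_of_view({0: always}, st, arm_of) == 0
    vis = np.ones(n, bool)
    vis[40:60] = False
    gone_once = traj(np.zeros(n), np.zeros(n), visible=vis)
    gone_once = gone_once[gone_once["visible"]]
    assert count_out_of_view({0: gone_once}, st, arm_of) == 1


def test_out_of_view_scheduled_exits(small_scene):
    from surgtrack.pipeline import gt_trajectories

    gt = small_scene.ground_truth
    trajs, st = gt_trajectories(gt)
    scheduled_active_exits = sum(
        1
        for f0, f1, i in gt.config.exit_events
        if gt.arm_of[i] in gt.active_arms(f0)
    )
    assert count_out_of_view(trajs, st, gt.arm_of) == scheduled_active_exits


# -- collisions ------------------------------------------------------------


def test_collision_counting():
    n = 50
    never = {
        0: {f: (0.0, 0.0, 5.0, 5.0) for f in range(n)},
        1: {f: (50.0, 50.0, 5.0, 5.0) for f in range(n)},
    }
    assert count_collisions(never, n) == 0
    once = {
        0: {f: (0.0, 0.0, 5.0, 5.0) for f in range(n)},
        1: {f: ((2.0, 2.0, 5.0, 5.0) if 20 <= f < 25 else (50.0, 50.0, 5.0, 5.0)) for f in range(n)},
    }
    assert count_collisions(once, n) == 1
    twice = {
        0: {f: (0.0, 0.0, 5.0, 5.0) for f in range(n)},
        1: {
            f: ((2.0, 2.0, 5.0, 5.0) if (10 <= f < 13 or 30 <= f < 34) else (50.0, 50.0, 5.0, 5.0))
            for f in range(n)
        },
    }
    assert count_collisions(twice, n) == 2


def test_collisions_mask_aware():
    m_diag = np.eye(11, dtype=bool)
    m_anti = np.fliplr(np.eye(11, dtype=bool))
    m_left = np.zeros((11, 11), bool)
    m_left[:, :2] = True
    m_right = np.zeros((11, 11), bool)
    m_right[:, -2:] = True
    crossing = {0: {0: ((0, 0, 11, 11), m_diag)}, 1: {0: ((0, 0, 11, 11), m_anti)}}
    apart = {0: {0: ((0, 0, 11, 11), m_left)}, 1: {0: ((0, 0, 11, 11), m_right)}}
    assert count_collisions(crossing, 1) == 1
    assert count_collisions(apart, 1) == 0


def test_scheduled_occlusions_counted(three_scene):
    from surgtrack.pipeline import gt_metrics

    gt = three_scene.ground_truth
    mv = gt_metrics(gt)
    assert mv.instrument_collisions >= len(gt.config.occlusion_events)


# -- movements and economic factor ----------------------------------------


def test_movements_stationary_and_single_glide():
    n = 100
    assert count_movements({0: traj(np.zeros(n), np.zeros(n))}, fps=10) == 0
    x = np.linspace(0, 100, n)
    assert count_movements({0: traj(x, np.zeros(n))}, fps=10) == 1


def test_movements_five_bursts():
    fps = 10.0
    seg = []
    for _ in range(5):
        seg.append(np.full(20, 0.0))  # pause 2 s
        seg.append(np.cumsum(np.full(10, 1.0)))  # burst at 10 mm/s for 1 s
    x = np.concatenate([np.zeros(1)] + seg)
    x = np.cumsum(np.diff(x, prepend=0.0) != 0) * 1.0  # monotone bursts
    assert (
        count_movements({0: traj(x, np.zeros(len(x)))}, fps=fps, speed_threshold=2.0)
        == 5
    )


def test_economic_factor_straight_is_one():
    x = np.linspace(0, 50, 100)
    assert economic_factor({0: traj(x, np.zeros(100))}, fps=10) == pytest.approx(
        1.0, abs=1e-6
    )


def test_economic_factor_half_circle():
    th = np.linspace(0, np.pi, 500)
    r = 10.0
    t = traj(r * np.cos(th), r * np.sin(th))
    assert economic_factor({0: t}, fps=50) == pytest.approx(2 / np.pi, abs=0.01)


def test_economic_factor_closed_loop_counts_as_zero():
    th = np.linspace(0, 2 * np.pi, 500)
    t = traj(10 * np.cos(th), 10 * np.sin(th))
    assert economic_factor({0: t}, fps=50) == pytest.approx(0.0, abs=0.02)


def test_economic_factor_without_episodes_is_nan():
    got = economic_factor({0: traj(np.zeros(50), np.zeros(50))}, fps=10)
    assert np.isnan(got)


# -- instrument changes and laparoscopy ------------------------------------


def test_instrument_changes():
    const = [frozenset({0, 1})] * 50
    assert count_instrument_changes(const) == 0
    one = [frozenset({0, 1})] * 25 + [frozenset({0, 2})] * 25
    assert count_instrument_changes(one) == 1
    two = [frozenset({0, 1})] * 10 + [frozenset({0, 2})] * 10 + [frozenset({0, 1})] * 10
    assert count_instrument_changes(two) == 2


def test_laparoscopy_usage():
    fps = 23.0
    assert laparoscopy_usage(states(100), fps) == (0, 0.0)
    n, dur = laparoscopy_usage(states(100, cam=range(40, 60)), fps)
    assert n == 1 and dur == pytest.approx(20 / 23)
    n, dur = laparoscopy_usage(states(100, cam=set(range(10, 20)) | set(range(70, 75))), fps)
    assert n == 2 and dur == pytest.approx(15 / 23)


# -- normalization ---------------------------------------------------------


def _metric_table(rows):
    return pd.DataFrame(rows, columns=METRIC_NAMES)


def test_normalizer_identical_rows_standardize_to_zero():
    row = [100.0, 2, 1, 500.0, 4.0, 10, 0.8, 1, 5.0]
    table = _metric_table([row, row, row])
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        z, _ = normalize_metrics(table)
        assert any("zero-variance" in str(x.message) for x in w)
    assert (z.to_numpy() == 0).all()


def test_normalizer_stage_one_is_rate_per_time():
    a = [100.0, 2, 1, 500.0, 4.0, 10, 0.8, 1, 5.0]
    b = list(a)
    b[0] = 200.0  # double duration, same motion -> half the rates
    table = _metric_table([a, b])
    s1 = MetricNormalizer._stage1(table)
    assert s1["economy_of_motion"].iloc[1] == pytest.approx(
        s1["economy_of_motion"].iloc[0] / 2
    )
    assert s1["average_speed"].iloc[1] == s1["average_speed"].iloc[0]
    assert s1["time_to_completion"].iloc[1] == 200.0


def test_normalizer_zscore_contract_and_reapplication():
    rng = np.random.default_rng(0)
    table = _metric_table(np.abs(rng.normal(5, 2, (30, 9))))
    norm = MetricNormalizer().fit(table)
    z = norm.transform(table)
    np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-9)
    np.testing.assert_allclose(z.std(axis=0, ddof=0), 1, atol=1e-9)
    again = MetricNormalizer.from_json(norm.to_json()).transform(table)
    np.testing.assert_allclose(again.to_numpy(), z.to_numpy(), atol=1e-12)


def test_normalizer_requires_cohort():
    with pytest.raises(ValueError):
        MetricNormalizer().fit(_metric_table([np.ones(9)]))
    with pytest.raises(ValueError):
        MetricNormalizer().transform(_metric_table([np.ones(9)]))
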