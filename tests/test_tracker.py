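"""Kalman filter, association and track lifecycle."""

import itertools

import numpy as np
import pytest

from surgtrack.detection import Detection, nms, oracle_detect
from surgtrack.tracker import (
    CONFIRMED,
    DELETED,
    LOST,
    Tracker,
    TrackerConfig,
    associate,
    box_to_measurement,
    iou,
    kalman_initiate,
    kalman_predict,
    kalman_update,
    measurement_to_box,
)


def _state(cx=10.0, cy=10.0, a=1.0, h=20.0, vx=0.0, vy=0.0):
    s = kalman_initiate((cx, cy, a, h))
    s.mean[4] = vx
    s.mean[5] = vy
    return s


# -- Kalman ----------------------------------------------------------------


def test_predict_advances_by_constant_velocity():
    s = kalman_predict(_state(cx=10, cy=10, vx=3, vy=0), dt=1)
    assert s.mean[0] == pytest.approx(13.0)
    assert s.mean[1] == pytest.approx(10.0)


def test_predict_zero_velocity_keeps_position_and_grows_covariance():
    s0 = _state()
    s1 = kalman_predict(s0)
    assert s1.mean[0] == s0.mean[0] and s1.mean[1] == s0.mean[1]
    assert np.trace(s1.covariance) > np.trace(s0.covariance)


def test_predict_rejects_zero_dt():
    with pytest.raises(ValueError):
        kalman_predict(_state(), dt=0)


def test_velocity_estimate_converges_on_noiseless_track():
    """Constant-velocity measurements drive the velocity estimate to truth."""
    v = 3.0
    s = kalman_initiate((0.0, 0.0, 1.0, 20.0))
    errs = []
    for k in range(1, 101):
        s = kalman_predict(s)
        s = kalman_update(s, (v * k, 0.0, 1.0, 20.0))
        if k in (50, 100):
            errs.append(abs(s.mean[4] - v))
    assert errs[0] < 2e-3  # near-converged after 50 noiseless steps
    assert errs[1] < 1e-5  # and geometrically decaying thereafter
    assert s.mean[5] == pytest.approx(0.0, abs=1e-6)


def test_update_with_zero_innovation_keeps_mean():
    s = kalman_predict(_state())
    s2 = kalman_update(s, s.mean[:4])
    np.testing.assert_allclose(s2.mean, s.mean, atol=1e-12)


def test_update_matches_independent_linear_algebra():
    """Posterior equals the closed-form Kalman correction computed by hand."""
    from surgtrack.tracker import _innovation_cov

    s = kalman_predict(_state(cx=5, cy=7, a=1.4, h=33))
    z = np.array([8.0, 6.0, 1.5, 30.0])
    H = np.eye(4, 8)
    S = _innovation_cov(s)
    K = s.covariance @ H.T @ np.linalg.inv(S)
    expected = s.mean + K @ (z - H @ s.mean)
    got = kalman_update(s, z)
    np.testing.assert_allclose(got.mean, expected, atol=1e-9)
    # measured-component variances never grow in the update
    assert np.trace(got.covariance[:4, :4]) <= np.trace(s.covariance[:4, :4]) + 1e-12


def test_update_rejects_nonpositive_height():
    with pytest.raises(ValueError):
        kalman_update(_state(), (0.0, 0.0, 1.0, 0.0))


def test_measurement_box_roundtrip():
    box = (3.0, 4.0, 10.0, 20.0)
    assert measurement_to_box(box_to_measurement(box)) == pytest.approx(box)


# -- IOU -------------------------------------------------------------------


def test_iou_identical_is_one():
    assert iou((2, 3, 10, 10), (2, 3, 10, 10)) == 1.0


def test_iou_disjoint_is_zero():
    assert iou((0, 0, 10, 10), (20, 20, 5, 5)) == 0.0


def test_iou_worked_example_and_symmetry():
    a, b = (0, 0, 10, 10), (5, 0, 10, 10)
    assert iou(a, b) == pytest.approx(1 / 3)
    assert iou(a, b) == iou(b, a)


def test_iou_degenerate_boxes_give_zero():
    assert iou((0, 0, 0, 0), (0, 0, 0, 0)) == 0.0


# -- Hungarian association -------------------------------------------------


def test_associate_single_pair():
    res = associate(np.array([[0.1]]))
    assert res.matches == [(0, 0)]


def test_associate_prefers_diagonal_on_symmetric_costs():
    res = associate(np.array([[0.1, 0.9], [0.9, 0.1]]))
    assert sorted(res.matches) == [(0, 0), (1, 1)]


def test_associate_equals_bruteforce_on_random_matrices():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(1, 5))
        C = rng.random((n, n))
        res = associate(C)
        got = sum(C[r, c] for r, c in res.matches)
        best = min(
            sum(C[i, p[i]] for i in range(n)) for p in itertools.permutations(range(n))
        )
        assert got == pytest.approx(best)


def test_associate_empty_inputs():
    res = associate(np.zeros((0, 0)))
    assert res.matches == [] and res.unmatched_tracks == []


def test_associate_drops_gated_matches():
    from surgtrack.tracker import GATED_COST

    C = np.array([[0.1, GATED_COST], [GATED_COST, GATED_COST]])
    res = associate(C)
    assert res.matches == [(0, 0)]
    assert res.unmatched_tracks == [1]
    assert res.unmatched_detections == [1]


# -- tracker lifecycle -----------------------------------------------------


def _box_det(frame, x, y, w=20, h=20, conf=1.0):
    return Detection(frame, (x, y, w, h), np.ones((h, w), bool), conf)


def test_two_clean_streams_give_two_stable_tracks(quiet_scene):
    gt = quiet_scene.ground_truth
    tr = Tracker(TrackerConfig())
    ids_seen = set()
    for f in range(gt.n_frames):
        dets = nms(oracle_detect(gt, f))
        tr.step(dets)
        ids_seen |= {t.track_id for t in tr.tracks}
        if f >= 2:
            assert len(tr.confirmed_tracks) == 2
    assert len(ids_seen) == 2
    # confirmed boxes equal the GT boxes at the final frame
    for t in tr.confirmed_tracks:
        d = t.history[-1][1]
        assert any(
            tuple(d.box) == tuple(g.box)
            for g in gt.per_frame[gt.n_frames - 1].values()
        )


def test_confirmed_track_cap_is_three():
    """Five persistent parallel detection streams never exceed 3 confirmed."""
    tr = Tracker(TrackerConfig())
    for f in range(40):
        dets = [_box_det(f, 30 + 60 * k, 30 + f) for k in range(5)]
        tr.step(dets)
        assert len(tr.confirmed_tracks) <= 3
    assert len(tr.confirmed_tracks) == 3


def test_blocked_confirmation_goes_through_when_slot_frees():
    tr = Tracker(TrackerConfig(max_age=3))
    for f in range(10):
        dets = [_box_det(f, 30 + 60 * k, 30) for k in range(4)]
        tr.step(dets)
    assert len(tr.confirmed_tracks) == 3
    blocked = [t for t in tr.tracks if t.status != CONFIRMED]
    assert len(blocked) == 1 and blocked[0].hits >= 3
    # drop one confirmed stream; the blocked track confirms once a slot frees
    victim_x = int(round(tr.confirmed_tracks[0].box[0]))
    for f in range(10, 20):
        dets = [
            _box_det(f, 30 + 60 * k, 30)
            for k in range(4)
            if abs(30 + 60 * k - victim_x) > 5
        ]
        tr.step(dets)
    assert blocked[0].status == CONFIRMED


def test_track_lost_then_deleted_and_reentry_spawns_new_track():
    tr = Tracker(TrackerConfig(max_age=5))
    for f in range(10):
        tr.step([_box_det(f, 100, 100)])
    (t0,) = tr.confirmed_tracks
    for f in range(10, 30):
        tr.step([])
    assert all(t.track_id != t0.track_id for t in tr.tracks)  # deleted
    for f in range(30, 36):
        tr.step([_box_det(f, 100, 100)])
    assert len(tr.confirmed_tracks) == 1
    assert tr.confirmed_tracks[0].track_id != t0.track_id
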