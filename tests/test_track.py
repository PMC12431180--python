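"""Tracker: IoU, Kalman filter limits, two-stage association, lifecycle."""

import itertools

import numpy as np
import pytest

from kernelflow import (ByteTracker, Detection, TrackerConfig, TrackStatus,
                        associate, iou, predict, run_tracker, update)
from kernelflow.track import KalmanBoxFilter, Track, _box_to_measurement

from conftest import crossing_pair_detections, straight_fall_detections, \
    truth_dict_to_table


# -- IoU --------------------------------------------------------------------


def test_iou_identical_boxes():
    assert iou((3, 4, 10, 12), (3, 4, 10, 12)) == 1.0


def test_iou_disjoint_boxes():
    assert iou((0, 0, 5, 5), (100, 100, 5, 5)) == 0.0


def test_iou_partial_overlap_hand_value():
    """(0,0,2,2) vs (1,1,2,2): intersection 1, union 7 -> 1/7."""
    assert iou((0, 0, 2, 2), (1, 1, 2, 2)) == pytest.approx(1 / 7)


def test_iou_symmetric_random():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = tuple(rng.uniform(0, 50, 2)) + tuple(rng.uniform(1, 30, 2))
        b = tuple(rng.uniform(0, 50, 2)) + tuple(rng.uniform(1, 30, 2))
        assert iou(a, b) == pytest.approx(iou(b, a))
        assert 0.0 <= iou(a, b) <= 1.0


def test_iou_rejects_degenerate_boxes():
    with pytest.raises(ValueError):
        iou((0, 0, 0, 5), (0, 0, 5, 5))


# -- Kalman filter ----------------------------------------------------------


def _make_track(box=(90, 90, 20, 20), config=None) -> Track:
    kf = KalmanBoxFilter(config or TrackerConfig())
    mean, cov = kf.initiate(_box_to_measurement(box))
    return Track(id=1, mean=mean, cov=cov, kf=kf, last_box=box)


def test_predict_zero_velocity_is_fixed_point():
    t = _make_track()
    cx, cy = t.center
    predict(t)
    assert t.center == (cx, cy)
    assert t.frames_since_update == 1


def test_predict_advances_by_velocity():
    t = _make_track()
    t.mean[5] = 3.0        # vy = 3 px/frame
    cy = t.mean[1]
    predict(t)
    assert t.mean[1] == pytest.approx(cy + 3.0)


def test_predict_tracks_parabolic_fall_within_2px():
    """After 5 predict/update cycles on y = g t^2 / 2, the one-step-ahead
    prediction lands within 2 px of the true next position."""
    g = 0.12
    cfg = TrackerConfig(measurement_scale=0.1)
    ys = [0.5 * g * t * t for t in range(8)]
    t = _make_track(box=(90, ys[0] - 10, 20, 20), config=cfg)
    for k in range(1, 6):
        predict(t)
        update(t, Detection(frame=k, box=(90, ys[k] - 10, 20, 20), confidence=1.0))
    predict(t)
    assert abs(t.mean[1] - ys[6]) < 2.0


def test_update_zero_measurement_noise_snaps_to_detection():
    t = _make_track(config=TrackerConfig(measurement_scale=1e-6))
    predict(t)
    update(t, Detection(frame=1, box=(120, 130, 20, 20), confidence=1.0))
    assert t.center == pytest.approx((130.0, 140.0), abs=1e-3)


def test_update_infinite_measurement_noise_keeps_prior():
    t = _make_track(config=TrackerConfig(measurement_scale=1e6))
    predict(t)
    prior = t.mean.copy()
    update(t, Detection(frame=1, box=(120, 130, 20, 20), confidence=1.0))
    assert t.mean[:2] == pytest.approx(prior[:2], abs=1e-3)


def test_repeated_updates_contract_covariance():
    t = _make_track()
    det = Detection(frame=0, box=(90, 90, 20, 20), confidence=1.0)
    traces = []
    for k in range(1, 6):
        t.mean, t.cov = t.kf.update(t.mean, t.cov, _box_to_measurement(det.box))
        traces.append(np.trace(t.cov))
    assert all(b <= a + 1e-9 for a, b in zip(traces, traces[1:]))


def test_covariance_stays_symmetric_psd():
    t = _make_track()
    rng = np.random.default_rng(1)
    for k in range(1, 20):
        predict(t)
        box = (90 + rng.normal(0, 2), 90 + 3 * k + rng.normal(0, 2), 20, 20)
        update(t, Detection(frame=k, box=box, confidence=1.0))
        assert np.allclose(t.cov, t.cov.T)
        assert np.linalg.eigvalsh(t.cov).min() > -1e-8


def test_gravity_compensation_keeps_coasting_on_ballistic_path():
    """A lost track coasting 15 frames stays near y = y0 + v t + g t^2/2."""
    g = 0.5
    t = _make_track(box=(90, 90, 20, 20), config=TrackerConfig(gravity=g))
    t.mean[5] = 2.0
    y0 = t.mean[1]
    for _ in range(15):
        predict(t)
    assert t.mean[1] == pytest.approx(y0 + 2.0 * 15 + 0.5 * g * 15 ** 2, rel=1e-9)


# -- association ------------------------------------------------------------


def test_high_confidence_match_in_stage_one():
    t = _make_track(box=(100, 100, 20, 20))
    d = Detection(frame=1, box=(102, 102, 20, 20), confidence=0.9)
    res = associate([t], [d], TrackerConfig())
    assert res.matches == [(t, d)]
    assert res.stage_of_match[t.id] == 1


def test_low_confidence_match_rescued_in_stage_two():
    """A track whose only evidence is a low-confidence box survives via the
    secondary association instead of going unmatched."""
    t = _make_track(box=(100, 100, 20, 20))
    t.status = TrackStatus.ACTIVE
    d = Detection(frame=1, box=(101, 101, 20, 20), confidence=0.3)
    res = associate([t], [d], TrackerConfig())
    assert res.matches == [(t, d)]
    assert res.stage_of_match[t.id] == 2
    assert res.unmatched_detections == []      # low conf never seeds tracks


def test_secondary_disabled_leaves_track_unmatched():
    t = _make_track(box=(100, 100, 20, 20))
    t.status = TrackStatus.ACTIVE
    d = Detection(frame=1, box=(101, 101, 20, 20), confidence=0.3)
    res = associate([t], [d], TrackerConfig(use_secondary=False))
    assert res.matches == [] and res.unmatched_tracks == [t]


def test_below_low_conf_detections_discarded():
    t = _make_track(box=(100, 100, 20, 20))
    t.status = TrackStatus.ACTIVE
    d = Detection(frame=1, box=(101, 101, 20, 20), confidence=0.05)
    res = associate([t], [d], TrackerConfig())
    assert res.matches == [] and res.unmatched_detections == []


def _brute_force_min_cost(mat: np.ndarray) -> float:
    n, m = mat.shape
    k = min(n, m)
    best = np.inf
    for rows in itertools.permutations(range(n), k):
        for cols in itertools.permutations(range(m), k):
            best = min(best, sum(mat[r, c] for r, c in zip(rows, cols)))
    return best


@pytest.mark.parametrize("seed", range(8))
def test_stage_one_assignment_is_globally_optimal(seed):
    """Stage-1 matching cost equals exhaustive minimum over permutations."""
    rng = np.random.default_rng(seed)
    n_t, n_d = rng.integers(1, 6, 2)
    tracks = []
    for i in range(n_t):
        t = _make_track(box=(rng.uniform(0, 80), rng.uniform(0, 80), 20, 20))
        t.id = i + 1
        t.status = TrackStatus.ACTIVE
        tracks.append(t)
    dets = [Detection(frame=1, box=(rng.uniform(0, 80), rng.uniform(0, 80), 20, 20),
                      confidence=0.9) for _ in range(n_d)]
    cfg = TrackerConfig(match_iou_first=1e-9)     # accept any overlapping pair
    res = associate(tracks, dets, cfg)
    cost = sum(1.0 - iou(t.box, d.box) for t, d in res.matches)
    mat = np.array([[1.0 - iou(t.box, d.box) for d in dets] for t in tracks])
    # pairs the gate rejected are exactly the zero-IoU (cost 1) assignments
    k = min(n_t, n_d)
    full_cost = cost + (k - len(res.matches)) * 1.0
    assert full_cost == pytest.approx(_brute_force_min_cost(mat), abs=1e-6)


def test_three_by_three_assignment_matches_permutation_oracle():
    """Hand-built 3x3 all-overlapping instance: optimal, not greedy."""
    positions = [(0.0, 0.0), (8.0, 0.0), (0.0, 8.0)]
    det_positions = [(6.0, 1.0), (1.0, 6.0), (2.0, 2.0)]
    tracks = []
    for i, (x, y) in enumerate(positions):
        t = _make_track(box=(x, y, 20, 20))
        t.id = i + 1
        t.status = TrackStatus.ACTIVE
        tracks.append(t)
    dets = [Detection(frame=1, box=(x, y, 20, 20), confidence=0.9)
            for x, y in det_positions]
    res = associate(tracks, dets, TrackerConfig(match_iou_first=1e-9))
    cost = sum(1.0 - iou(t.box, d.box) for t, d in res.matches)
    mat = np.array([[1.0 - iou(t.box, d.box) for d in dets] for t in tracks])
    assert len(res.matches) == 3
    assert cost == pytest.approx(_brute_force_min_cost(mat), abs=1e-12)


# -- lifecycle / end-to-end -------------------------------------------------


def test_single_kernel_single_id():
    dets = straight_fall_detections(30)
    tracks = run_tracker(dets)
    assert tracks["id"].nunique() == 1


def test_gap_shorter_than_max_lost_keeps_id():
    dets = straight_fall_detections(40, drop_frames=set(range(15, 25)))
    tracks = run_tracker(dets, TrackerConfig(max_frames_lost=30))
    assert tracks["id"].nunique() == 1
    frames = set(tracks["frame"])
    assert 14 in frames and 25 in frames


def test_gap_longer_than_max_lost_spawns_new_id():
    dets = straight_fall_detections(60, drop_frames=set(range(10, 25)))
    tracks = run_tracker(dets, TrackerConfig(max_frames_lost=5))
    assert tracks["id"].nunique() == 2
    assert sorted(tracks["id"].unique()) == [1, 2]    # ids increase, never reused


def test_track_ids_strictly_increasing_at_creation():
    tracker = ByteTracker()
    for f in range(1, 6):
        # two fresh far-apart detections per frame that never re-associate
        tracker.step([Detection(frame=f, box=(100 * f, 10, 20, 20), confidence=0.9),
                      Detection(frame=f, box=(100 * f, 300, 20, 20), confidence=0.9)],
                     frame=f)
    ids = [t.id for t in tracker.tracks]
    assert ids == sorted(ids) and len(set(ids)) == len(ids)


def test_out_of_order_frames_rejected():
    tracker = ByteTracker()
    tracker.step([], frame=5)
    with pytest.raises(ValueError, match="increas"):
        tracker.step([], frame=4)
    dets = [Detection(frame=3, box=(0, 0, 5, 5), confidence=0.9),
            Detection(frame=2, box=(0, 0, 5, 5), confidence=0.9)]
    with pytest.raises(ValueError, match="order"):
        run_tracker(dets)


def test_tentative_track_needs_min_hits_to_emit():
    dets = straight_fall_detections(10)
    tracks = run_tracker(dets, TrackerConfig(min_hits=2))
    assert tracks["frame"].min() == 2      # first frame only initiates


def test_status_transition_rules_enforced():
    t = _make_track()
    with pytest.raises(ValueError, match="transition"):
        t._transition(TrackStatus.LOST)    # tentative cannot go lost directly


def test_secondary_association_prevents_identity_switch():
    """On the crossing fixture with a confidence dip, the two-stage tracker
    keeps both identities; stage-1-only re-identifies at least once more."""
    from kernelflow import id_switches
    dets, truth = crossing_pair_detections()
    gt = truth_dict_to_table(truth)
    ids_two = id_switches(run_tracker(dets, TrackerConfig()), gt)
    ids_one = id_switches(run_tracker(dets, TrackerConfig(use_secondary=False)), gt)
    assert ids_two < ids_one


def test_invalid_tracker_config_rejected():
    with pytest.raises(ValueError):
        TrackerConfig(high_conf=0.3, low_conf=0.5).validate()
    with pytest.raises(ValueError):
        TrackerConfig(match_iou_first=0.0).validate()
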