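"""Metrics: matching, precision/recall, average precision, counting accuracy,
identity switches — each checked against small independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from kernelflow import (Detection, MatchResult, MetricsReport,
                        average_precision, counting_accuracy, id_switches,
                        iou, match_detections, mean_ap, precision, recall,
                        truncate_percent)


def _det(frame, l, t, w=10, h=10, conf=1.0):
    return Detection(frame=frame, box=(l, t, w, h), confidence=conf)


# -- matching ---------------------------------------------------------------


def test_perfect_predictions_no_errors():
    truths = [_det(1, 0, 0), _det(1, 50, 50), _det(2, 10, 10)]
    m = match_detections(truths, truths)
    assert (m.tp, m.fp, m.fn) == (3, 0, 0)


def test_no_predictions_all_missed():
    truths = [_det(1, 0, 0), _det(1, 50, 50)]
    m = match_detections([], truths)
    assert (m.tp, m.fp, m.fn) == (0, 0, 2)


def _brute_force_max_matching(preds, truths, thr=0.5):
    """Maximum number of one-to-one pred-truth pairs with IoU >= thr."""
    best = 0
    idx = range(len(truths))
    for k in range(min(len(preds), len(truths)), 0, -1):
        for psel in itertools.permutations(range(len(preds)), k):
            for tsel in itertools.permutations(idx, k):
                ok = all(preds[p].frame == truths[t].frame
                         and iou(preds[p].box, truths[t].box) >= thr
                         for p, t in zip(psel, tsel))
                if ok:
                    return k
    return best


def test_three_preds_two_truths_matches_brute_force():
    truths = [_det(1, 0, 0), _det(1, 20, 0)]
    preds = [_det(1, 1, 0, conf=0.9),        # good for truth 0
             _det(1, 21, 1, conf=0.8),       # good for truth 1
             _det(1, 60, 60, conf=0.7)]      # spurious
    m = match_detections(preds, truths)
    assert m.tp == _brute_force_max_matching(preds, truths) == 2
    assert (m.fp, m.fn) == (1, 0)


def test_counts_partition_predictions_and_truths():
    rng = np.random.default_rng(2)
    truths = [_det(1, x, y) for x, y in rng.uniform(0, 200, (6, 2))]
    preds = [_det(1, x + rng.normal(0, 4), y + rng.normal(0, 4), conf=c)
             for (x, y, _), c in zip(
                 [(t.box[0], t.box[1], 0) for t in truths],
                 rng.uniform(0.3, 1.0, 6))]
    m = match_detections(preds, truths)
    assert m.tp + m.fp == len(preds)
    assert m.tp + m.fn == len(truths)


# -- precision / recall -----------------------------------------------------


def test_precision_recall_arithmetic():
    m = MatchResult(tp=3, fp=1, fn=1)
    assert precision(m) == pytest.approx(0.75)
    assert recall(m) == pytest.approx(0.75)
    perfect = MatchResult(tp=4, fp=0, fn=0)
    assert precision(perfect) == recall(perfect) == 1.0
    assert recall(MatchResult(tp=0, fp=0, fn=5)) == 0.0


def test_zero_over_zero_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        assert recall(MatchResult(tp=0, fp=3, fn=0)) == 0.0
    with pytest.warns(UserWarning):
        assert precision(MatchResult(tp=0, fp=0, fn=3)) == 0.0


# -- average precision ------------------------------------------------------


def test_ap_is_one_when_all_predictions_correct():
    truths = [_det(1, 0, 0), _det(1, 40, 40), _det(2, 10, 10)]
    preds = [_det(1, 1, 1, conf=0.4), _det(1, 41, 40, conf=0.9),
             _det(2, 10, 11, conf=0.6)]
    assert average_precision(preds, truths) == 1.0


def test_ap_zero_for_single_wrong_prediction():
    assert average_precision([_det(1, 100, 100, conf=0.9)], [_det(1, 0, 0)]) == 0.0


def test_ap_empty_truths_is_an_error():
    with pytest.raises(ValueError):
        average_precision([_det(1, 0, 0, conf=0.5)], [])


def _step_area_ap(flags, n_truth):
    """Independent PR-curve area: interpolated precision envelope, summed
    over recall steps."""
    tp = fp = 0
    points = [(0.0, 1.0)]
    for ok in flags:
        tp, fp = tp + ok, fp + (not ok)
        points.append((tp / n_truth, tp / (tp + fp)))
    area = 0.0
    for i, (r, _) in enumerate(points[1:], start=1):
        r_prev = points[i - 1][0]
        p_env = max(p for (rr, p) in points[i:])
        area += (r - r_prev) * p_env
    return area


def test_ap_matches_hand_step_area_on_mixed_ranking():
    """5 predictions, flags (T,F,T,T,F) over 4 truths: AP = 0.625 by hand."""
    truths = [_det(1, 0, 0), _det(1, 40, 0), _det(1, 80, 0), _det(1, 120, 0)]
    preds = [_det(1, 0, 1, conf=0.9),          # hit
             _det(1, 200, 200, conf=0.8),      # miss
             _det(1, 40, 1, conf=0.7),         # hit
             _det(1, 80, 1, conf=0.6),         # hit
             _det(1, 240, 240, conf=0.5)]      # miss
    ap = average_precision(preds, truths)
    assert ap == pytest.approx(_step_area_ap([1, 0, 1, 1, 0], 4))
    assert ap == pytest.approx(0.625)


def test_map_single_class_equals_ap():
    assert mean_ap([0.731]) == pytest.approx(0.731)
    assert mean_ap([0.5, 1.0]) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        mean_ap([])


# -- counting accuracy ------------------------------------------------------


@pytest.mark.parametrize("pred, true, pct", [
    (300, 300, 100.0),
    (0, 300, 0.0),
])
def test_counting_accuracy_exact_cases(pred, true, pct):
    assert counting_accuracy(pred, true) == pytest.approx(pct)


def test_counting_accuracy_truncates_for_display():
    raw = counting_accuracy(299, 300)
    assert raw == pytest.approx(100 * 299 / 300)        # 99.666...
    assert truncate_percent(raw) == 99.6                # printed form


def test_counting_accuracy_symmetric_in_over_and_under_count():
    assert counting_accuracy(290, 300) == counting_accuracy(310, 300)


def test_counting_accuracy_requires_positive_truth():
    with pytest.raises(ValueError):
        counting_accuracy(5, 0)


# -- identity switches ------------------------------------------------------


def _table(rows):
    return pd.DataFrame(rows, columns=["frame", "id", "left", "top",
                                       "width", "height", "conf"])


def test_perfect_single_track_has_no_switches():
    gt = _table([(f, 1, 0, 10 * f, 10, 10, 1.0) for f in range(1, 10)])
    assert id_switches(gt, gt) == 0


def test_single_reassignment_counts_one_switch():
    gt = _table([(f, 1, 0, 10 * f, 10, 10, 1.0) for f in range(1, 7)])
    trk = _table([(f, 4 if f <= 3 else 9, 0, 10 * f, 10, 10, 1.0)
                  for f in range(1, 7)])
    assert id_switches(trk, gt) == 1


def test_two_object_crossing_switch_count_matches_hand_enumeration():
    """Two objects pass each other; tracker swaps ids at the meeting point
    and one object is later re-identified again: 3 assignment changes."""
    gt_rows, trk_rows = [], []
    for f in range(1, 11):
        gt_rows += [(f, 1, 0, 10 * f, 10, 10, 1.0),
                    (f, 2, 0, 110 - 10 * f, 10, 10, 1.0)]
        id_a, id_b = (11, 12) if f <= 5 else (12, 11)   # swap at f=6
        if f >= 9:
            id_a = 13                                   # re-id of object 1
        trk_rows += [(f, id_a, 0, 10 * f, 10, 10, 1.0),
                     (f, id_b, 0, 110 - 10 * f, 10, 10, 1.0)]
    # hand enumeration: obj1: 11->12 (f6), 12->13 (f9); obj2: 12->11 (f6)
    assert id_switches(_table(trk_rows), _table(gt_rows)) == 3


def test_metrics_report_validation():
    with pytest.raises(ValueError):
        MetricsReport(precision=1.2, recall=0.5, ap=0.5, map=0.5,
                      counting_accuracy=99.0, id_switches=0)
    r = MetricsReport(precision=0.998, recall=0.996, ap=0.998, map=0.998,
                      counting_accuracy=99.67, id_switches=2)
    d = r.to_dict()
    assert d["counting_accuracy_display"] == 99.6
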