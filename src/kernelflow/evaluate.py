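"""Evaluation metrics for detection, tracking and counting.

Detection quality is summarized by recall TP/(TP+FN), precision
TP/(TP+FP), and average precision — the area under the precision-recall
curve swept over detection confidence, AP = integral of P(r) dr with
all-points interpolation.  mAP is the unweighted mean of per-class AP;
with a single kernel class, mAP equals AP.

Counting quality uses the trial-level statistic
accuracy = 1 - |predicted - true| / true (as a percentage), and tracking
stability is summarized by the number of identity switches: events where
the track id assigned to one ground-truth object changes between its
consecutive matched frames.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detect import Detection
from .track import iou, iou_matrix

__all__ = [
    "MatchResult", "MetricsReport", "match_detections", "precision", "recall",
    "average_precision", "mean_ap", "counting_accuracy", "truncate_percent",
    "id_switches",
]


@dataclass
class MatchResult:
    """TP/FP/FN at a fixed IoU threshold, plus per-prediction flags.

    ``flags`` holds one boolean per prediction in descending-confidence
    order (True = matched a ground-truth box), the ordering AP needs.
    """

    tp: int
    fp: int
    fn: int
    flags: list[bool] = field(default_factory=list)
    confidences: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def _group_by_frame(dets: Sequence[Detection]) -> dict[int, list[Detection]]:
    out: dict[int, list[Detection]] = {}
    for d in dets:
        out.setdefault(d.frame, []).append(d)
    return out


def match_detections(preds: Sequence[Detection], truths: Sequence[Detection],
                     iou_threshold: float = 0.5) -> MatchResult:
    """Greedy confidence-descending matching of predictions to ground truth.

    Predictions are visited from highest to lowest confidence; each claims
    the unmatched same-frame truth with the largest IoU at or above the
    threshold.  Each truth is matched at most once.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError(f"iou_threshold must be in (0, 1), got {iou_threshold}")
    truth_by_frame = _group_by_frame(truths)
    matched: dict[int, set[int]] = {f: set() for f in truth_by_frame}
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    flags: list[bool] = []
    confs: list[float] = []
    tp = 0
    for i in order:
        p = preds[i]
        candidates = truth_by_frame.get(p.frame, [])
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(candidates):
            if j in matched[p.frame]:
                continue
            v = iou(p.box, t.box)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        ok = best_j >= 0
        if ok:
            matched[p.frame].add(best_j)
            tp += 1
        flags.append(ok)
        confs.append(p.confidence)
    fp = len(preds) - tp
    fn = len(truths) - tp
    return MatchResult(tp=tp, fp=fp, fn=fn, flags=flags, confidences=confs)


def recall(m: MatchResult) -> float:
    denom = m.tp + m.fn
    if denom == 0:
        warnings.warn("recall 0/0: no ground-truth objects; returning 0", stacklevel=2)
        return 0.0
    return m.tp / denom


def precision(m: MatchResult) -> float:
    denom = m.tp + m.fp
    if denom == 0:
        warnings.warn("precision 0/0: no predictions; returning 0", stacklevel=2)
        return 0.0
    return m.tp / denom


def average_precision(preds: Sequence[Detection], truths: Sequence[Detection],
                      iou_threshold: float = 0.5) -> float:
    """Area under the precision-recall curve (all-points interpolation)."""
    if len(truths) == 0:
        raise ValueError("average precision undefined without ground-truth objects")
    if len(preds) == 0:
        return 0.0
    m = match_detections(preds, truths, iou_threshold)
    flags = np.array(m.flags, dtype=float)
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(1.0 - flags)
    rec = tp_cum / len(truths)
    prec = tp_cum / (tp_cum + fp_cum)
    # precision envelope from the right, then sum step areas over recall
    rec = np.concatenate(([0.0], rec))
    prec = np.concatenate(([1.0], prec))
    for i in range(len(prec) - 2, -1, -1):
        prec[i] = max(prec[i], prec[i + 1])
    return float(np.sum((rec[1:] - rec[:-1]) * prec[1:]))


def mean_ap(per_class_aps: Sequence[float]) -> float:
    """Unweighted mean of per-class average precisions."""
    if len(per_class_aps) == 0:
        raise ValueError("mean_ap of zero classes is undefined")
    return float(np.mean(per_class_aps))


def counting_accuracy(predicted: int, true: int) -> float:
    """Trial counting accuracy 1 - |predicted - true| / true, in percent."""
    if true <= 0:
        raise ValueError(f"true count must be > 0, got {true}")
    return 100.0 * (1.0 - abs(predicted - true) / true)


def truncate_percent(value: float, decimals: int = 1) -> float:
    """Truncate (not round) a percentage for display, e.g. 99.67 -> 99.6."""
    factor = 10 ** decimals
    return math.floor(value * factor) / factor


def _as_frame_table(obj) -> pd.DataFrame:
    if isinstance(obj, (str, Path)):
        from .mot import read_table
        return read_table(obj)
    return obj


def id_switches(tracks: pd.DataFrame | str | Path,
                truth: pd.DataFrame | str | Path,
                iou_threshold: float = 0.5) -> int:
    """Count identity switches of tracker output against ground truth.

    Per frame, tracks are assigned to truth objects by maximum-IoU optimal
    assignment (pairs below the threshold rejected); a switch is counted
    whenever the track id assigned to one truth id differs between that
    truth id's consecutive matched frames.
    """
    trk = _as_frame_table(tracks)
    gt = _as_frame_table(truth)
    assigned: dict[int, int] = {}       # truth id -> last matched track id
    switches = 0
    gt_by_frame = dict(tuple(gt.groupby("frame")))
    trk_by_frame = dict(tuple(trk.groupby("frame")))
    for f in sorted(gt_by_frame):
        g = gt_by_frame[f]
        t = trk_by_frame.get(f)
        if t is None or len(t) == 0:
            continue
        g_boxes = list(zip(g["left"], g["top"], g["width"], g["height"]))
        t_boxes = list(zip(t["left"], t["top"], t["width"], t["height"]))
        mat = iou_matrix(g_boxes, t_boxes)
        rows, cols = linear_sum_assignment(-mat)
        for r, c in zip(rows, cols):
            if mat[r, c] < iou_threshold:
                continue
            truth_id = int(g["id"].iloc[r])
            track_id = int(t["id"].iloc[c])
            if truth_id in assigned and assigned[truth_id] != track_id:
                switches += 1
            assigned[truth_id] = track_id
    return switches


@dataclass
class MetricsReport:
    """Consolidated detection / tracking / counting metrics for one trial."""

    precision: float
    recall: float
    ap: float
    map: float
    counting_accuracy: float
    id_switches: int

    def __post_init__(self) -> None:
        for name in ("precision", "recall", "ap", "map"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.id_switches < 0:
            raise ValueError("id_switches must be >= 0")

    def to_dict(self) -> dict:
        return {
            "precision": round(self.precision, 3),
            "recall": round(self.recall, 3),
            "ap": round(self.ap, 3),
            "map": round(self.map, 3),
            "counting_accuracy": self.counting_accuracy,
            "counting_accuracy_display": truncate_percent(self.counting_accuracy),
            "id_switches": self.id_switches,
        }
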