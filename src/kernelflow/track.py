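"""Hierarchical tracking-by-detection with a constant-velocity Kalman filter.

The tracker follows the ByteTrack association scheme: every live track is
propagated one frame by an 8-state Kalman filter (center x, center y,
aspect ratio w/h, height, and their per-frame velocities); high-confidence
detections are matched to tracks first by minimum-cost linear assignment
on 1 - IoU; the tracks left over are then given a second chance against
the low-confidence detections that a single-stage tracker would discard.
That second stage is what keeps identities alive through occlusion dips,
when a detector still fires on a partially hidden kernel but with low
confidence.

Track identities are positive integers, strictly increasing at creation
and never reused within a tracker instance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import linear_sum_assignment

from .detect import Detection

__all__ = [
    "TrackerConfig", "TrackStatus", "Track", "KalmanBoxFilter", "ByteTracker",
    "iou", "iou_matrix", "predict", "update", "associate", "AssociationResult",
    "run_tracker",
]

Box = tuple[float, float, float, float]   # (left, top, width, height)


# ---------------------------------------------------------------------------
# geometry


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection over union of two (left, top, width, height) boxes."""
    la, ta, wa, ha = box_a
    lb, tb, wb, hb = box_b
    if wa <= 0 or ha <= 0 or wb <= 0 or hb <= 0:
        raise ValueError(f"box dimensions must be positive: {box_a}, {box_b}")
    ix = max(0.0, min(la + wa, lb + wb) - max(la, lb))
    iy = max(0.0, min(ta + ha, tb + hb) - max(ta, tb))
    inter = ix * iy
    union = wa * ha + wb * hb - inter
    return inter / union


def iou_matrix(boxes_a: Sequence[Box], boxes_b: Sequence[Box]) -> np.ndarray:
    out = np.zeros((len(boxes_a), len(boxes_b)))
    for i, a in enumerate(boxes_a):
        for j, b in enumerate(boxes_b):
            out[i, j] = iou(a, b)
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TrackerConfig:
    """Association thresholds and Kalman noise scales.

    Defaults are the reference ByteTrack settings: detections at or above
    ``high_conf`` drive the first association stage; those in
    ``[low_conf, high_conf)`` are only used to rescue unmatched tracks;
    anything below ``low_conf`` is discarded.  New tracks are seeded only
    by unmatched high-confidence detections scoring at least
    ``new_track_conf``.  Noise scales are proportional to box height, the
    usual parameterization for this filter family.
    """

    high_conf: float = 0.5
    low_conf: float = 0.1
    match_iou_first: float = 0.2
    match_iou_second: float = 0.5
    new_track_conf: float = 0.6
    max_frames_lost: int = 30
    min_hits: int = 2
    std_weight_position: float = 1.0 / 20.0
    std_weight_velocity: float = 1.0 / 160.0
    measurement_scale: float = 1.0
    use_secondary: bool = True       # disable to get a stage-1-only tracker
    gravity: float | None = None     # px/frame^2 ballistic compensation (None/0 = pure CV)

    def validate(self) -> None:
        if not (0.0 < self.low_conf < self.high_conf <= 1.0):
            raise ValueError(
                f"need 0 < low_conf < high_conf <= 1, got {self.low_conf}, {self.high_conf}")
        for name in ("match_iou_first", "match_iou_second", "new_track_conf"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.max_frames_lost < 0 or self.min_hits < 1:
            raise ValueError("max_frames_lost must be >= 0 and min_hits >= 1")


# ---------------------------------------------------------------------------
# Kalman filter


class KalmanBoxFilter:
    """Constant-velocity Kalman filter on (cx, cy, aspect, height).

    State is the 8-vector (cx, cy, a, h, vcx, vcy, va, vh) with unit
    per-frame time steps.  Process and measurement noise standard
    deviations scale with the current box height, so large (near) kernels
    tolerate proportionally larger innovations than small (far) ones.

    When ``config.gravity`` is set, prediction adds the known ballistic
    acceleration to the vertical channel as a control input (a
    constant-acceleration variant).  At genuine high-speed frame rates the
    per-frame acceleration is negligible and pure constant velocity
    suffices; at a reduced frame-rate equivalent the known gravity keeps
    coasting predictions on the ballistic path through detection gaps.
    """

    _ndim = 4

    def __init__(self, config: TrackerConfig | None = None):
        cfg = config or TrackerConfig()
        self._std_pos = cfg.std_weight_position
        self._std_vel = cfg.std_weight_velocity
        self._meas_scale = cfg.measurement_scale
        self._gravity = cfg.gravity or 0.0
        self.F = np.eye(8)
        for i in range(4):
            self.F[i, i + 4] = 1.0
        self.H = np.eye(4, 8)

    def initiate(self, measurement: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Start a track from an unassociated measurement (zero velocity)."""
        mean = np.zeros(8)
        mean[:4] = measurement
        h = measurement[3]
        std = [2 * self._std_pos * h, 2 * self._std_pos * h, 1e-2, 2 * self._std_pos * h,
               10 * self._std_vel * h, 10 * self._std_vel * h, 1e-5, 10 * self._std_vel * h]
        cov = np.diag(np.square(std))
        return mean, cov

    def predict(self, mean: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = mean[3]
        std = [self._std_pos * h, self._std_pos * h, 1e-2, self._std_pos * h,
               self._std_vel * h, self._std_vel * h, 1e-5, self._std_vel * h]
        Q = np.diag(np.square(std))
        mean = self.F @ mean
        if self._gravity:
            mean[1] += 0.5 * self._gravity     # cy: + g/2 over the step
            mean[5] += self._gravity           # vcy: + g
        cov = self.F @ cov @ self.F.T + Q
        return mean, cov

    def _measurement_cov(self, mean: np.ndarray) -> np.ndarray:
        h = mean[3]
        std = np.array([self._std_pos * h, self._std_pos * h, 1e-1, self._std_pos * h])
        return np.diag(np.square(std * self._meas_scale))

    def update(self, mean: np.ndarray, cov: np.ndarray,
               measurement: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        R = self._measurement_cov(mean)
        S = self.H @ cov @ self.H.T + R
        chol, lower = scipy.linalg.cho_factor(S, check_finite=False)
        K = scipy.linalg.cho_solve((chol, lower), (cov @ self.H.T).T,
                                   check_finite=False).T
        innovation = measurement - self.H @ mean
        new_mean = mean + K @ innovation
        new_cov = cov - K @ S @ K.T
        new_cov = 0.5 * (new_cov + new_cov.T)       # keep symmetric PSD
        return new_mean, new_cov


def _box_to_measurement(box: Box) -> np.ndarray:
    l, t, w, h = box
    return np.array([l + w / 2.0, t + h / 2.0, w / h, h])


def _measurement_to_box(z: np.ndarray) -> Box:
    cx, cy, a, h = z[:4]
    w = a * h
    return (cx - w / 2.0, cy - h / 2.0, w, h)


# ---------------------------------------------------------------------------
# tracks


class TrackStatus(enum.Enum):
    TENTATIVE = "tentative"
    ACTIVE = "active"
    LOST = "lost"
    REMOVED = "removed"


_ALLOWED_TRANSITIONS = {
    (TrackStatus.TENTATIVE, TrackStatus.ACTIVE),
    (TrackStatus.TENTATIVE, TrackStatus.REMOVED),
    (TrackStatus.ACTIVE, TrackStatus.LOST),
    (TrackStatus.LOST, TrackStatus.ACTIVE),
    (TrackStatus.LOST, TrackStatus.REMOVED),
}


@dataclass(eq=False)
class Track:
    """A persistent kernel identity with Kalman state and history."""

    id: int
    mean: np.ndarray
    cov: np.ndarray
    kf: KalmanBoxFilter
    status: TrackStatus = TrackStatus.TENTATIVE
    last_box: Box | None = None
    last_conf: float = 0.0
    frames_since_update: int = 0
    hits: int = 1
    history: list[tuple[int, float, float, Box]] = field(default_factory=list)

    @property
    def box(self) -> Box:
        """Current state estimate as a (left, top, width, height) box."""
        return _measurement_to_box(self.mean)

    @property
    def center(self) -> tuple[float, float]:
        return (float(self.mean[0]), float(self.mean[1]))

    def _transition(self, new: TrackStatus) -> None:
        if new is self.status:
            return
        if (self.status, new) not in _ALLOWED_TRANSITIONS:
            raise ValueError(f"illegal track transition {self.status} -> {new}")
        self.status = new


def predict(track: Track) -> Track:
    """Advance a track one frame under the constant-velocity model."""
    if track.status is TrackStatus.REMOVED:
        raise ValueError(f"cannot predict removed track {track.id}")
    track.mean, track.cov = track.kf.predict(track.mean, track.cov)
    # aspect and height must stay positive for box conversion
    track.mean[2] = max(track.mean[2], 1e-4)
    track.mean[3] = max(track.mean[3], 1.0)
    track.frames_since_update += 1
    return track


def update(track: Track, det: Detection, frame: int | None = None,
           min_hits: int = 2) -> Track:
    """Kalman measurement update from an associated detection."""
    z = _box_to_measurement(det.box)
    track.mean, track.cov = track.kf.update(track.mean, track.cov, z)
    track.mean[2] = max(track.mean[2], 1e-4)
    track.mean[3] = max(track.mean[3], 1.0)
    track.last_box = det.box
    track.last_conf = det.confidence
    track.frames_since_update = 0
    track.hits += 1
    if track.status is TrackStatus.TENTATIVE and track.hits >= min_hits:
        track._transition(TrackStatus.ACTIVE)
    elif track.status is TrackStatus.LOST:
        track._transition(TrackStatus.ACTIVE)
    if frame is not None:
        if track.history and frame <= track.history[-1][0]:
            raise ValueError(f"history frames must increase for track {track.id}")
        cx, cy = track.center
        track.history.append((frame, cx, cy, track.box))
    return track


# ---------------------------------------------------------------------------
# association


@dataclass
class AssociationResult:
    matches: list[tuple[Track, Detection]]
    unmatched_tracks: list[Track]
    unmatched_detections: list[Detection]
    stage_of_match: dict[int, int] = field(default_factory=dict)  # track id -> 1|2


def _match_stage(tracks: list[Track], dets: list[Detection],
                 iou_threshold: float) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost assignment on 1 - IoU, rejecting pairs below the threshold."""
    if not tracks or not dets:
        return [], list(range(len(tracks))), list(range(len(dets)))
    mat = iou_matrix([t.box for t in tracks], [d.box for d in dets])
    rows, cols = linear_sum_assignment(1.0 - mat)
    matches, um_t, um_d = [], set(range(len(tracks))), set(range(len(dets)))
    for r, c in zip(rows, cols):
        if mat[r, c] >= iou_threshold:
            matches.append((r, c))
            um_t.discard(r)
            um_d.discard(c)
    return matches, sorted(um_t), sorted(um_d)


def associate(tracks: Sequence[Track], detections: Sequence[Detection],
              config: TrackerConfig | None = None) -> AssociationResult:
    """Two-stage data association.

    Stage 1 assigns high-confidence detections (conf >= ``high_conf``) to
    all live tracks by optimal linear assignment on 1 - IoU, accepting
    pairs with IoU >= ``match_iou_first``.  Stage 2 offers the
    low-confidence detections (conf in [``low_conf``, ``high_conf``)) to
    the remaining unmatched active/lost tracks at the stricter
    ``match_iou_second`` gate.  Detections below ``low_conf`` are dropped;
    low-confidence detections never appear among the unmatched leftovers
    (they cannot seed tracks).  Tracks are processed in id order so that
    equal-cost assignments resolve toward the lowest id.
    """
    cfg = config or TrackerConfig()
    cfg.validate()
    pool = sorted((t for t in tracks if t.status is not TrackStatus.REMOVED),
                  key=lambda t: t.id)
    high = [d for d in detections if d.confidence >= cfg.high_conf]
    low = [d for d in detections if cfg.low_conf <= d.confidence < cfg.high_conf]

    m1, um_t1, um_d1 = _match_stage(pool, high, cfg.match_iou_first)
    matches = [(pool[r], high[c]) for r, c in m1]
    stage = {pool[r].id: 1 for r, _ in m1}

    leftovers = [pool[i] for i in um_t1]
    unmatched_tracks: list[Track] = []
    if cfg.use_secondary and low:
        second_pool = [t for t in leftovers
                       if t.status in (TrackStatus.ACTIVE, TrackStatus.LOST)]
        excluded = [t for t in leftovers if t not in second_pool]
        m2, um_t2, _ = _match_stage(second_pool, low, cfg.match_iou_second)
        matches.extend((second_pool[r], low[c]) for r, c in m2)
        stage.update({second_pool[r].id: 2 for r, _ in m2})
        unmatched_tracks = [second_pool[i] for i in um_t2] + excluded
    else:
        unmatched_tracks = leftovers

    unmatched_dets = [high[i] for i in um_d1]
    return AssociationResult(matches=matches,
                             unmatched_tracks=sorted(unmatched_tracks, key=lambda t: t.id),
                             unmatched_detections=unmatched_dets,
                             stage_of_match=stage)


# ---------------------------------------------------------------------------
# tracker


class ByteTracker:
    """Frame-by-frame multi-object tracker with two-stage association."""

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.config.validate()
        self.kf = KalmanBoxFilter(self.config)
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame = 0

    def _new_track(self, det: Detection) -> Track:
        mean, cov = self.kf.initiate(_box_to_measurement(det.box))
        t = Track(id=self._next_id, mean=mean, cov=cov, kf=self.kf,
                  last_box=det.box, last_conf=det.confidence)
        self._next_id += 1
        return t

    def step(self, detections: Sequence[Detection], frame: int | None = None
             ) -> list[Track]:
        """Process one frame of detections; returns the active-track snapshots."""
        if frame is None:
            frame = self._last_frame + 1
        if frame <= self._last_frame:
            raise ValueError(f"frames must be strictly increasing: got {frame} "
                             f"after {self._last_frame}")
        self._last_frame = frame
        cfg = self.config

        live = [t for t in self.tracks if t.status is not TrackStatus.REMOVED]
        for t in live:
            predict(t)

        result = associate(live, detections, cfg)
        for track, det in result.matches:
            update(track, det, frame=frame, min_hits=cfg.min_hits)

        for track in result.unmatched_tracks:
            if track.status is TrackStatus.TENTATIVE:
                track._transition(TrackStatus.REMOVED)
            elif track.status is TrackStatus.ACTIVE:
                track._transition(TrackStatus.LOST)
            if (track.status is TrackStatus.LOST
                    and track.frames_since_update > cfg.max_frames_lost):
                track._transition(TrackStatus.REMOVED)

        for det in result.unmatched_detections:
            if det.confidence >= cfg.new_track_conf:
                t = self._new_track(det)
                if cfg.min_hits <= 1:
                    t._transition(TrackStatus.ACTIVE)
                    cx, cy = t.center
                    t.history.append((frame, cx, cy, t.box))
                self.tracks.append(t)

        self.tracks = [t for t in self.tracks if t.status is not TrackStatus.REMOVED]
        return [t for t in self.tracks
                if t.status is TrackStatus.ACTIVE and t.frames_since_update == 0]


def run_tracker(detections: Iterable[Detection],
                config: TrackerConfig | None = None,
                n_frames: int | None = None) -> pd.DataFrame:
    """Run the tracker over a detection stream; returns MOT-style track rows.

    Detections must be ordered by (non-decreasing) frame; every frame index
    from 1 to the last detection frame (or ``n_frames``) is stepped, so
    tracks coast through empty frames.  Output columns:
    frame, id, left, top, width, height, conf.
    """
    by_frame: dict[int, list[Detection]] = {}
    last = 0
    prev = 0
    for d in detections:
        if d.frame < prev:
            raise ValueError(f"detections out of order: frame {d.frame} after {prev}")
        prev = d.frame
        by_frame.setdefault(d.frame, []).append(d)
        last = max(last, d.frame)
    if n_frames is not None:
        last = max(last, n_frames)

    tracker = ByteTracker(config)
    rows = []
    for f in range(1, last + 1):
        for t in tracker.step(by_frame.get(f, ()), frame=f):
            l, tp, w, h = t.box
            rows.append((f, t.id, l, tp, w, h, t.last_conf))
    return pd.DataFrame(rows, columns=["frame", "id", "left", "top",
                                       "width", "height", "conf"])
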