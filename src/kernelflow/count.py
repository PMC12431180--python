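"""Line-crossing counting of tracked identities.

A virtual horizontal counting line is placed across the fall path at
height ``y0``.  A tracked identity is counted exactly once, at the first
frame where its stored center height was strictly above the line
(y < y0) and its current center height is strictly below it (y > y0) —
remember that image y grows downward, so "below the line" means larger y.

Because a count requires the *same* identity to be seen on both sides of
the line at two different times, identity churn is largely harmless: an
identity switch after a track has crossed cannot produce a second count
(each id counts at most once and the replacement id starts below the
line), and a switch before the crossing simply lets the replacement id
cross instead.  This is what makes the counter far more reliable than
counting distinct track ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["CountingLine", "CountState", "Crossing", "update_counter",
           "count_scene", "default_line"]


@dataclass(frozen=True)
class Crossing:
    id: int
    frame: int
    x: float       # center x linearly interpolated at the crossing instant


@dataclass
class CountingLine:
    """The counting segment A=(x_a, y0) .. B=(x_b, y0).

    With ``enforce_x_extent`` False (the default) any crossing of the
    height y0 counts; with it True the interpolated x at the crossing
    instant must lie within [x_a, x_b].
    """

    y0: float
    x_a: float = float("-inf")
    x_b: float = float("inf")
    enforce_x_extent: bool = False

    def validate(self, frame_height: float | None = None) -> None:
        if self.enforce_x_extent and not (self.x_a < self.x_b):
            raise ValueError(f"need x_a < x_b, got {self.x_a}, {self.x_b}")
        if self.y0 < 0:
            raise ValueError(f"y0 must be >= 0, got {self.y0}")
        if frame_height is not None and self.y0 >= frame_height:
            raise ValueError(f"y0={self.y0} outside frame height {frame_height}")


def default_line(frame_size: tuple[int, int]) -> CountingLine:
    """Default placement: 60% of the way down, spanning the full width."""
    w, h = frame_size
    return CountingLine(y0=0.6 * h, x_a=0.0, x_b=float(w - 1))


@dataclass
class CountState:
    """Per-scene crossing ledger: ids already counted and last-seen heights."""

    counted_ids: set[int] = field(default_factory=set)
    last_pos: dict[int, tuple[float, float, int]] = field(default_factory=dict)
    # id -> (cx, cy, frame) at the most recent usable observation
    total: int = 0
    crossings: list[Crossing] = field(default_factory=list)


def update_counter(state: CountState,
                   frame_tracks: Sequence[tuple[int, float, float]],
                   line: CountingLine,
                   frame: int = -1) -> CountState:
    """Fold one frame of track centers (id, cx, cy) into the count state.

    A count fires for an id whose stored y is strictly above the line and
    whose current y is strictly below it; an id is never counted twice.  A
    sample landing exactly on the line satisfies neither strict
    inequality: it neither counts nor overwrites the stored height, so the
    decision is deferred to the next observation.
    """
    seen = set()
    for obj_id, cx, cy in frame_tracks:
        if obj_id in seen:
            raise ValueError(f"duplicate id {obj_id} within frame {frame}")
        seen.add(obj_id)
        prior = state.last_pos.get(obj_id)
        if cy == line.y0:
            continue            # on-line sample: defer, keep the stored height
        if (prior is not None and obj_id not in state.counted_ids
                and prior[1] < line.y0 and cy > line.y0):
            px, py, _ = prior
            x_cross = px + (cx - px) * (line.y0 - py) / (cy - py)
            if not line.enforce_x_extent or (line.x_a <= x_cross <= line.x_b):
                state.counted_ids.add(obj_id)
                state.total += 1
                state.crossings.append(Crossing(id=obj_id, frame=frame, x=x_cross))
        state.last_pos[obj_id] = (cx, cy, frame)
    return state


def count_scene(tracks: pd.DataFrame | str | Path | Iterable[tuple],
                line: CountingLine) -> CountState:
    """Count crossings over a whole scene of track rows.

    Accepts a MOT track file path, a DataFrame with frame/id/left/top/
    width/height columns, or an iterable of (frame, id, cx, cy) rows.
    Frames must be non-decreasing.
    """
    line.validate()
    if isinstance(tracks, (str, Path)):
        from .mot import read_table
        tracks = read_table(tracks)
    if isinstance(tracks, pd.DataFrame):
        rows = [(int(r.frame), int(r.id),
                 float(r.left) + float(r.width) / 2.0,
                 float(r.top) + float(r.height) / 2.0)
                for r in tracks.itertuples(index=False)]
    else:
        rows = [(int(f), int(i), float(x), float(y)) for f, i, x, y in tracks]

    state = CountState()
    current_frame: int | None = None
    batch: list[tuple[int, float, float]] = []
    for f, obj_id, cx, cy in rows:
        if current_frame is not None and f < current_frame:
            raise ValueError(f"track rows not sorted by frame: {f} after {current_frame}")
        if f != current_frame:
            if batch:
                update_counter(state, batch, line, frame=current_frame)
            batch = []
            current_frame = f
        batch.append((obj_id, cx, cy))
    if batch:
        update_counter(state, batch, line, frame=current_frame)
    return state


def write_counts(state: CountState, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "total": state.total,
        "crossings": [{"id": c.id, "frame": c.frame, "x": round(c.x, 2)}
                      for c in state.crossings],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path
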