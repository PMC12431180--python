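"""Readers and writers for MOT-Challenge plain-text tables.

One row per object per frame:
``frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z`` with 1-based frame
indices.  Detection files carry ``id = -1``; ground-truth files carry
``conf = 1``; the trailing ``x,y,z`` world coordinates are unused here and
written as ``-1``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .detect import Detection

__all__ = [
    "MOTParseError",
    "read_detections",
    "write_detections",
    "read_table",
    "write_tracks",
]

_TRACK_COLUMNS = ["frame", "id", "left", "top", "width", "height", "conf"]


class MOTParseError(ValueError):
    """Malformed MOT text row, reported with its line number."""


def _parse_line(line: str, lineno: int, path) -> tuple:
    parts = line.split(",")
    if len(parts) < 7:
        raise MOTParseError(f"{path}:{lineno}: expected >= 7 comma-separated fields, "
                            f"got {len(parts)}: {line!r}")
    try:
        frame = int(float(parts[0]))
        obj_id = int(float(parts[1]))
        left, top, width, height, conf = (float(p) for p in parts[2:7])
    except ValueError as exc:
        raise MOTParseError(f"{path}:{lineno}: non-numeric field in {line!r}") from exc
    return frame, obj_id, left, top, width, height, conf


def read_detections(path: str | Path) -> list[Detection]:
    """Read a MOT detection file (id column ignored) into Detection objects."""
    out: list[Detection] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            frame, _, left, top, width, height, conf = _parse_line(line, lineno, path)
            try:
                out.append(Detection(frame=frame, box=(left, top, width, height),
                                     confidence=conf))
            except ValueError as exc:
                raise MOTParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_detections(detections: Iterable[Detection], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for d in detections:
            l, t, w, h = d.box
            fh.write(f"{d.frame},-1,{l:.2f},{t:.2f},{w:.2f},{h:.2f},"
                     f"{d.confidence:.4f},-1,-1,-1\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a MOT track/ground-truth file into a frame/id/box/conf DataFrame."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            rows.append(_parse_line(line, lineno, path))
    df = pd.DataFrame(rows, columns=_TRACK_COLUMNS)
    return df


def write_tracks(rows: pd.DataFrame | Sequence[tuple], path: str | Path) -> Path:
    """Write track rows (frame, id, left, top, width, height, conf) as MOT text."""
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        rows = list(rows[_TRACK_COLUMNS].itertuples(index=False))
    with open(path, "w") as fh:
        for r in rows:
            frame, obj_id, l, t, w, h, conf = r[:7]
            fh.write(f"{int(frame)},{int(obj_id)},{l:.2f},{t:.2f},{w:.2f},{h:.2f},"
                     f"{conf:.4f},-1,-1,-1\n")
    return path
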