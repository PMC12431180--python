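"""Shared fixtures: small deterministic scenes and constructed fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from kernelflow import Detection, SimConfig, simulate_scene
from kernelflow.simulate import AugmentConfig


def small_sim_config(seed: int = 0, n_kernels: int = 10, **overrides) -> SimConfig:
    """A fast, fully valid scene configuration: smaller view, same physics."""
    kwargs = dict(
        frame_size=(384, 320),
        n_kernels=n_kernels,
        density_target=5.0,
        release_x_range=(30.0, 190.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_scene():
    """A 12-kernel scene used by several read-only tests."""
    return simulate_scene(small_sim_config(seed=42, n_kernels=12))


@pytest.fixture
def identity_augment():
    """Augmentation config that is the identity transform."""
    return AugmentConfig(brightness_range=(0.0, 0.0), contrast_range=(1.0, 1.0),
                         noise_sigma=0.0, scale_range=(1.0, 1.0))


def straight_fall_detections(n_frames: int, x: float = 100.0, y0: float = 10.0,
                             vy: float = 4.0, size: float = 20.0,
                             conf: float = 0.9,
                             drop_frames: set[int] | None = None,
                             low_frames: set[int] | None = None,
                             low_conf: float = 0.3) -> list[Detection]:
    """Constant-velocity falling detections, optionally with gaps/conf dips."""
    drop = drop_frames or set()
    low = low_frames or set()
    out = []
    for f in range(1, n_frames + 1):
        if f in drop:
            continue
        y = y0 + vy * (f - 1)
        c = low_conf if f in low else conf
        out.append(Detection(frame=f, box=(x - size / 2, y - size / 2, size, size),
                             confidence=c))
    return out


def crossing_pair_detections(n_frames: int = 42, vy: float = 4.0,
                             dip: tuple[int, int] | None = (18, 28),
                             dip_conf: float = 0.3) -> tuple[list[Detection], dict]:
    """Two falling kernels; one dips to low confidence while turning.

    Kernel A moves left-to-right, kernel B right-to-left; during the dip
    window B's detections carry low confidence *and* B's horizontal
    velocity changes, so a tracker that discards low-confidence boxes
    coasts on a stale velocity and must re-identify B afterwards, while a
    two-stage tracker keeps updating through the dip.  Returns the
    detections plus the truth rows {frame: [(truth_id, box), ...]}.
    """
    size = 20.0
    dets: list[Detection] = []
    truth: dict[int, list[tuple[int, tuple]]] = {}
    xb = 260.0
    vxb = -3.0
    for f in range(1, n_frames + 1):
        y = 5.0 + vy * (f - 1)
        xa = 40.0 + 3.0 * (f - 1)
        if dip and f == dip[0]:
            vxb = -1.0                     # B eases off while barely visible
        if f > 1:
            xb += vxb
        boxes = {1: (xa - size / 2, y - size / 2, size, size),
                 2: (xb - size / 2, y + 60 - size / 2, size, size)}
        truth[f] = [(tid, b) for tid, b in boxes.items()]
        dets.append(Detection(frame=f, box=boxes[1], confidence=0.9))
        in_dip = dip is not None and dip[0] <= f <= dip[1]
        dets.append(Detection(frame=f, box=boxes[2],
                              confidence=dip_conf if in_dip else 0.9))
    return dets, truth


def truth_dict_to_table(truth: dict[int, list[tuple[int, tuple]]]):
    import pandas as pd
    rows = [(f, tid, b[0], b[1], b[2], b[3], 1.0)
            for f, items in truth.items() for tid, b in items]
    return pd.DataFrame(rows, columns=["frame", "id", "left", "top",
                                       "width", "height", "conf"])
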