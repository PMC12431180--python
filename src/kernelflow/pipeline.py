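"""End-to-end orchestration: simulate -> detect -> track -> count -> evaluate.

`run_pipeline` executes one full trial from a single configuration object
and returns (and optionally writes) a consolidated report;
`replicate_trials` repeats the trial over a list of seeds and aggregates
the per-trial counting accuracies and the cumulative counting error, the
batch-level protocol used to qualify the counter.

Everything downstream of the configuration is deterministic given its
seed; every artifact written to disk can be regenerated from the
configuration alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .count import CountingLine, count_scene, default_line, write_counts
from .detect import Detection, DetectorParams, default_detector_params, detect_frame
from .evaluate import (MetricsReport, average_precision, counting_accuracy,
                       id_switches, match_detections, precision, recall)
from .mot import write_detections, write_tracks
from .simulate import Scene, SimConfig, simulate_scene, write_scene
from .track import ByteTracker, TrackerConfig

__all__ = ["PipelineConfig", "run_pipeline", "replicate_trials"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Nested configuration for one counting trial.

    ``detector`` and ``line`` default to values derived from the
    simulation configuration (threshold midway between background and
    kernel intensity; counting line at 60% of the frame height).  The
    global seed lives on ``sim.seed`` and drives every stochastic stage.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    detector: DetectorParams | None = None
    line: CountingLine | None = None
    iou_threshold: float = 0.5
    outdir: str | Path | None = None
    save_frames: bool = False

    @property
    def seed(self) -> int:
        return self.sim.seed

    def resolved_detector(self) -> DetectorParams:
        return self.detector or default_detector_params(self.sim)

    def resolved_tracker(self) -> TrackerConfig:
        """Tracker config with ballistic compensation inherited from the scene.

        A tracker deployed on free-falling objects knows the (scaled)
        gravity of its scene; if ``tracker.gravity`` is left unset it is
        filled in from the simulation so coasting predictions stay on the
        ballistic path at the reduced frame-rate equivalent.
        """
        if self.tracker.gravity is None:
            return dataclasses.replace(self.tracker, gravity=self.sim.gravity)
        return self.tracker

    def resolved_line(self) -> CountingLine:
        return self.line or default_line(self.sim.frame_size)

    def validate(self) -> None:
        self.sim.validate()
        self.tracker.validate()
        self.resolved_detector().validate()
        self.resolved_line().validate(frame_height=self.sim.frame_size[1])
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError(f"iou_threshold must be in (0, 1), got {self.iou_threshold}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "sim": self.sim.to_dict(),
            "tracker": dataclasses.asdict(self.tracker),
            "iou_threshold": self.iou_threshold,
            "save_frames": self.save_frames,
        }
        if self.detector is not None:
            d["detector"] = dataclasses.asdict(self.detector)
        if self.line is not None:
            d["line"] = dataclasses.asdict(self.line)
        if self.outdir is not None:
            d["outdir"] = str(self.outdir)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs: dict = {}
        if "sim" in d:
            kwargs["sim"] = SimConfig.from_dict(d["sim"])
        if "tracker" in d:
            kwargs["tracker"] = TrackerConfig(**d["tracker"])
        if "detector" in d:
            kwargs["detector"] = DetectorParams(**d["detector"])
        if "line" in d:
            kwargs["line"] = CountingLine(**d["line"])
        for k in ("iou_threshold", "outdir", "save_frames"):
            if k in d:
                kwargs[k] = d[k]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _truth_as_detections(scene: Scene) -> list[Detection]:
    return [Detection(frame=int(r.frame),
                      box=(float(r.left), float(r.top),
                           float(r.width), float(r.height)),
                      confidence=1.0)
            for r in scene.truth.itertuples(index=False)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute one full trial and return the consolidated report.

    Stages: scene simulation, per-frame blob detection, two-stage
    tracking, line-crossing counting, and evaluation against the exact
    simulator ground truth.  Frames are rendered, consumed and discarded
    one at a time.  Raises with the failing stage named if any stage
    errors out.
    """
    config.validate()
    stage = "simulate"
    try:
        scene = simulate_scene(config.sim)
        logger.info("simulate: %d kernels over %d frames (seed %d)",
                    len(scene.kernels), scene.n_frames, config.seed)

        stage = "detect/track"
        det_params = config.resolved_detector()
        tracker = ByteTracker(config.resolved_tracker())
        detections: list[Detection] = []
        rows = []
        for f in range(1, scene.n_frames + 1):
            img = scene.render(f)
            dets = detect_frame(img, det_params, frame=f)
            detections.extend(dets)
            for t in tracker.step(dets, frame=f):
                l, tp, w, h = t.box
                rows.append((f, t.id, l, tp, w, h, t.last_conf))
        tracks = pd.DataFrame(rows, columns=["frame", "id", "left", "top",
                                             "width", "height", "conf"])
        logger.info("detect/track: %d detections, %d track rows, %d ids",
                    len(detections), len(tracks),
                    tracks["id"].nunique() if len(tracks) else 0)

        stage = "count"
        line = config.resolved_line()
        state = count_scene(tracks, line)
        logger.info("count: %d crossings at y0=%.1f", state.total, line.y0)

        stage = "evaluate"
        truth_dets = _truth_as_detections(scene)
        m = match_detections(detections, truth_dets, config.iou_threshold)
        ap = average_precision(detections, truth_dets, config.iou_threshold)
        ids = id_switches(tracks, scene.truth, config.iou_threshold)
        true_count = len(scene.kernels)
        acc = counting_accuracy(state.total, true_count)
        report_metrics = MetricsReport(precision=precision(m), recall=recall(m),
                                       ap=ap, map=ap, counting_accuracy=acc,
                                       id_switches=ids)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    report = {
        "seed": config.seed,
        "n_kernels": true_count,
        "n_frames": scene.n_frames,
        "true_count": true_count,
        "predicted_count": state.total,
        "track_ids": int(tracks["id"].nunique()) if len(tracks) else 0,
        "metrics": report_metrics.to_dict(),
        "line_y0": line.y0,
    }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_scene(scene, outdir, frames=config.save_frames)
        write_detections(detections, outdir / "det.txt")
        write_tracks(tracks, outdir / "tracks.txt")
        write_counts(state, outdir / "counts.json")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def replicate_trials(config: PipelineConfig, seeds: Sequence[int]) -> dict:
    """Run one trial per seed and aggregate the batch statistics.

    Returns per-trial rows (trial, seed, true, predicted, accuracy and its
    one-decimal truncated display value) plus the cumulative counting
    error |sum(predicted) - sum(true)| / sum(true) as a percentage.
    """
    if len(seeds) < 1:
        raise ValueError("need at least one trial seed")
    trials = []
    for i, seed in enumerate(seeds, start=1):
        cfg = dataclasses.replace(
            config,
            sim=dataclasses.replace(config.sim, seed=int(seed)),
            outdir=(Path(config.outdir) / f"trial_{i}" if config.outdir else None),
        )
        report = run_pipeline(cfg)
        trials.append({
            "trial": i,
            "seed": int(seed),
            "true_count": report["true_count"],
            "predicted_count": report["predicted_count"],
            "accuracy": report["metrics"]["counting_accuracy"],
            "accuracy_display": report["metrics"]["counting_accuracy_display"],
            "id_switches": report["metrics"]["id_switches"],
        })
        logger.info("trial %d (seed %d): %d/%d counted (%.2f%%)",
                    i, seed, report["predicted_count"], report["true_count"],
                    report["metrics"]["counting_accuracy"])
    total_true = sum(t["true_count"] for t in trials)
    total_pred = sum(t["predicted_count"] for t in trials)
    cum_err = 100.0 * abs(total_pred - total_true) / total_true
    summary = {
        "trials": trials,
        "total_true": total_true,
        "total_predicted": total_pred,
        "cumulative_error_pct": cum_err,
        "min_accuracy": min(t["accuracy"] for t in trials),
        "mean_accuracy": sum(t["accuracy"] for t in trials) / len(trials),
    }
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary
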