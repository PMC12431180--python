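"""Synthetic falling-kernel scene generation.

Emulates the acquisition geometry of a seed-kernel batch counter: kernels
drop off a conveyor edge, undergo projectile motion in front of a
monochromatic backdrop, and are filmed by a fixed overhead high-speed
camera.  Each scene consists of rendered grayscale frames plus an exact
ground-truth trajectory table, so detectors and trackers can be evaluated
without any real footage.

Conventions: image origin at the top-left with y increasing downward, so a
falling kernel has strictly increasing center y.  All kinematic quantities
are expressed per frame at the configured frame-rate equivalent.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse
from skimage.transform import rescale as _rescale

__all__ = [
    "ReleaseBand",
    "KernelSpec",
    "AugmentConfig",
    "SimConfig",
    "Scene",
    "SimConfigError",
    "simulate_scene",
    "render_frame",
    "augment",
    "write_scene",
]

TRUTH_COLUMNS = [
    "frame", "id", "cx", "cy", "left", "top", "width", "height", "visibility",
]


class SimConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


class ReleaseBand(enum.Enum):
    """Vertical release position relative to the conveyor exit plane."""

    ABOVE_PLANE = "above_plane"
    AT_PLANE = "at_plane"
    BELOW_PLANE = "below_plane"


_BAND_ORDER = (ReleaseBand.ABOVE_PLANE, ReleaseBand.AT_PLANE, ReleaseBand.BELOW_PLANE)


@dataclass(frozen=True)
class KernelSpec:
    """One simulated kernel: geometry, photometry and release state."""

    id: int
    semi_axes: tuple[float, float]          # (a, b) px, a >= b > 0
    intensity: int                          # gray level 0..255
    release_time: int                       # frame index (0-based)
    release_point: tuple[float, float]      # (x, y) px
    release_band: ReleaseBand
    initial_velocity: tuple[float, float]   # (vx, vy) px/frame
    spin: float                             # rad/frame
    initial_angle: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise SimConfigError(f"semi_axes must satisfy a >= b > 0, got {self.semi_axes}")

@dataclass
class AugmentConfig:
    """Photometric/geometric perturbation ranges applied to rendered frames.

    Mirrors the augmentations used to diversify the original training
    imagery: random brightness and contrast adjustment, additive Gaussian
    noise, and isotropic rescaling.  Flips and rotations are deliberately
    absent: kernels fall under gravity, so mirrored or rotated frames would
    present physically implausible poses.
    """

    brightness_range: tuple[float, float] = (-10.0, 10.0)
    contrast_range: tuple[float, float] = (0.92, 1.08)
    noise_sigma: float = 3.0
    scale_range: tuple[float, float] = (1.0, 1.0)
    prob: float = 1.0

    def validate(self) -> None:
        for name in ("brightness_range", "contrast_range", "scale_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise SimConfigError(f"augment.{name} is empty: {(lo, hi)}")
        if self.noise_sigma < 0:
            raise SimConfigError(f"augment.noise_sigma must be >= 0, got {self.noise_sigma}")
        if not (0.0 <= self.prob <= 1.0):
            raise SimConfigError(f"augment.prob must be in [0, 1], got {self.prob}")


@dataclass
class SimConfig:
    """Scene generator parameters.

    Defaults encode the study conditions at a reduced frame-rate
    equivalent: a 768x512 view at ~0.5 mm/px filmed at a 120 fps
    equivalent, a conveyor running at 25 rpm on a 5 cm roller
    (~0.13 m/s -> ~2.2 px/frame exit speed), gravity reduced so kernels
    move a few pixels per frame (preserving the small inter-frame motion
    of genuine high-speed capture), and a mean density of 5-10 kernels
    per frame.
    """

    frame_size: tuple[int, int] = (768, 512)        # (W, H)
    fps_equivalent: float = 120.0
    gravity: float = 0.12                            # px / frame^2
    conveyor_exit_speed: float = 2.2                 # px / frame
    density_target: float = 5.0                      # mean kernels per frame
    n_kernels: int = 300
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    background_level: int = 20
    seed: int = 0
    # kernel geometry and photometry
    semi_major_range: tuple[float, float] = (8.0, 12.0)
    aspect_range: tuple[float, float] = (1.2, 2.0)
    intensity_range: tuple[int, int] = (120, 220)
    min_intensity_margin: int = 60
    spin_range: tuple[float, float] = (-0.15, 0.15)
    # release protocol: three vertical bands cycled per kernel
    release_x_range: tuple[float, float] = (30.0, 530.0)
    band_offset: float = 40.0                        # px between release bands
    vx_jitter: float = 1.0                           # px/frame, uniform
    vy0_range: tuple[float, float] = (0.0, 2.5)      # px/frame at release
    apply_augment: bool = True

    def validate(self) -> None:
        w, h = self.frame_size
        if w <= 0 or h <= 0:
            raise SimConfigError(f"frame_size must be positive, got {self.frame_size}")
        if self.n_kernels < 1:
            raise SimConfigError(f"n_kernels must be >= 1, got {self.n_kernels}")
        if self.gravity <= 0:
            raise SimConfigError(f"gravity must be > 0, got {self.gravity}")
        if self.density_target <= 0:
            raise SimConfigError(f"density_target must be > 0, got {self.density_target}")
        for name in ("semi_major_range", "aspect_range", "intensity_range",
                     "spin_range", "release_x_range", "vy0_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise SimConfigError(f"{name} is empty: {(lo, hi)}")
        if self.semi_major_range[0] <= 0:
            raise SimConfigError("semi_major_range must be positive")
        if self.aspect_range[0] < 1.0:
            raise SimConfigError("aspect_range must be >= 1 (a >= b)")
        lo_i = self.intensity_range[0]
        if abs(lo_i - self.background_level) < self.min_intensity_margin:
            raise SimConfigError(
                "intensity_range too close to background_level "
                f"(margin {abs(lo_i - self.background_level)} < {self.min_intensity_margin})"
            )
        self.augment.validate()

    # -- derived quantities -------------------------------------------------

    def band_release_y(self, band: ReleaseBand) -> float:
        if band is ReleaseBand.ABOVE_PLANE:
            return -self.band_offset
        if band is ReleaseBand.AT_PLANE:
            return 0.0
        return self.band_offset

    def mean_visible_residence(self) -> float:
        """Expected number of frames a kernel spends (partly) in view."""
        h = self.frame_size[1]
        a_mean = 0.5 * (self.semi_major_range[0] + self.semi_major_range[1])
        vy0 = 0.5 * (self.vy0_range[0] + self.vy0_range[1])
        g = self.gravity
        total = 0.0
        for band in _BAND_ORDER:
            y0 = self.band_release_y(band)
            # time from release until the top edge of the kernel passes H
            t_exit = _time_to_reach(h + a_mean - y0, vy0, g)
            # time until the bottom edge first enters the frame (y > -a)
            t_enter = _time_to_reach(-a_mean - y0, vy0, g) if y0 < -a_mean else 0.0
            total += t_exit - t_enter
        return total / len(_BAND_ORDER)

    def arrival_rate(self) -> float:
        """Poisson release rate (kernels/frame) matching density_target."""
        return self.density_target / self.mean_visible_residence()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["augment"] = dataclasses.asdict(self.augment)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "augment" in d and isinstance(d["augment"], dict):
            d["augment"] = AugmentConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["augment"].items()
            })
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


def _time_to_reach(distance: float, v0: float, g: float) -> float:
    """Frames for a body with initial speed v0 and acceleration g to fall `distance`."""
    if distance <= 0:
        return 0.0
    return (-v0 + math.sqrt(v0 * v0 + 2.0 * g * distance)) / g


# ---------------------------------------------------------------------------
# rendering


def _ellipse_pixels(cx: float, cy: float, a: float, b: float, angle: float):
    """Raster coordinates of a rotated ellipse, unclipped (may be negative)."""
    return _draw_ellipse(cy, cx, b, a, rotation=angle)


def render_frame(
    poses: Sequence[tuple[KernelSpec, float, float, float]],
    config: SimConfig,
    frame: int | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Rasterize one frame from per-kernel poses.

    ``poses`` is a sequence of ``(spec, cx, cy, angle)``; later entries are
    nearer to the camera and painted on top (painter's algorithm).  Returns
    the uint8 image and the per-kernel truth records.  Visibility is the
    fraction of each kernel's total elliptical area that is both inside the
    frame and not covered by a nearer kernel; kernels with no visible pixel
    produce no record.
    """
    w, h = config.frame_size
    canvas = np.full((h, w), -1, dtype=np.int32)
    totals: list[int] = []
    extents: list[tuple[int, int, int, int] | None] = []
    for idx, (spec, cx, cy, angle) in enumerate(poses):
        a, b = spec.semi_axes
        rr, cc = _ellipse_pixels(cx, cy, a, b, angle)
        totals.append(len(rr))
        if len(rr) == 0:
            extents.append(None)
            continue
        extents.append((int(cc.min()), int(rr.min()), int(cc.max()), int(rr.max())))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[keep], cc[keep]] = idx

    image = np.full((h, w), config.background_level, dtype=np.uint8)
    visible_counts = np.bincount(canvas[canvas >= 0].ravel(), minlength=len(poses))
    drawn = canvas >= 0
    if drawn.any():
        intensities = np.array([spec.intensity for spec, *_ in poses], dtype=np.uint8)
        image[drawn] = intensities[canvas[drawn]]

    records: list[dict] = []
    for idx, (spec, cx, cy, angle) in enumerate(poses):
        if totals[idx] == 0 or visible_counts[idx] == 0 or extents[idx] is None:
            continue
        x_min, y_min, x_max, y_max = extents[idx]
        left = max(0, x_min)
        top = max(0, y_min)
        right = min(w - 1, x_max)
        bottom = min(h - 1, y_max)
        if right < left or bottom < top:
            continue
        records.append({
            "frame": frame if frame is not None else -1,
            "id": spec.id,
            "cx": float(cx),
            "cy": float(cy),
            "left": left,
            "top": top,
            "width": right - left + 1,
            "height": bottom - top + 1,
            "visibility": float(visible_counts[idx] / totals[idx]),
        })
    return image, records


def augment(
    image: np.ndarray,
    config: AugmentConfig | None = None,
    rng: np.random.Generator | int | None = None,
    noise_pool: np.ndarray | None = None,
) -> np.ndarray:
    """Apply photometric/scale perturbations to a grayscale frame.

    Each transform fires with probability ``config.prob`` and samples its
    parameter uniformly from the configured range: brightness shift,
    contrast gain about mid-gray, additive Gaussian noise, isotropic
    rescale about the image center (cropped/padded back to the original
    size).  Degenerate ranges at the identity leave the image untouched.

    ``noise_pool`` optionally provides a pre-drawn bank of unit-normal
    float32 samples; the noise field is then a randomly offset slice of
    the pool instead of a fresh draw, which is considerably cheaper when
    augmenting thousands of frames of one scene.
    """
    cfg = config or AugmentConfig()
    cfg.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = image.astype(np.float32)

    if rng.random() < cfg.prob:
        out += np.float32(rng.uniform(*cfg.brightness_range))
    if rng.random() < cfg.prob:
        gain = np.float32(rng.uniform(*cfg.contrast_range))
        out -= 128.0
        out *= gain
        out += 128.0
    if cfg.noise_sigma > 0 and rng.random() < cfg.prob:
        if noise_pool is not None and noise_pool.size > out.size:
            off = int(rng.integers(0, noise_pool.size - out.size))
            noise = noise_pool[off:off + out.size].reshape(out.shape).copy()
        else:
            noise = rng.standard_normal(out.shape, dtype=np.float32)
        noise *= np.float32(cfg.noise_sigma)
        out += noise
    if rng.random() < cfg.prob:
        s = rng.uniform(*cfg.scale_range)
        if s != 1.0:
            out = _rescale_keep_shape(out, s, fill=float(np.median(out)))
    np.clip(out, 0, 255, out=out)
    return np.rint(out).astype(np.uint8)


def _rescale_keep_shape(img: np.ndarray, s: float, fill: float) -> np.ndarray:
    h, w = img.shape
    scaled = _rescale(img, s, order=1, preserve_range=True, anti_aliasing=s < 1.0)
    sh, sw = scaled.shape
    out = np.full((h, w), fill, dtype=np.float32)
    # center-crop or center-pad back to (h, w)
    src_r = max(0, (sh - h) // 2)
    src_c = max(0, (sw - w) // 2)
    dst_r = max(0, (h - sh) // 2)
    dst_c = max(0, (w - sw) // 2)
    nr = min(h, sh)
    nc = min(w, sw)
    out[dst_r:dst_r + nr, dst_c:dst_c + nc] = scaled[src_r:src_r + nr, src_c:src_c + nc]
    return out


# ---------------------------------------------------------------------------
# scene assembly


class FrameSequence:
    """Lazy, random-access list of rendered frames.

    Frames are rasterized (and augmented) on demand so that long scenes
    never hold all frames in memory; indexing is deterministic for a fixed
    scene seed regardless of access order.
    """

    def __init__(self, scene: "Scene"):
        self._scene = scene

    def __len__(self) -> int:
        return self._scene.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        n = len(self)
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(n))]
        if i < 0:
            i += n
        if not (0 <= i < n):
            raise IndexError(i)
        return self._scene.render(i + 1)

    def __iter__(self) -> Iterator[np.ndarray]:
        for i in range(len(self)):
            yield self[i]


@dataclass
class Scene:
    """Simulator output: lazy frames, exact truth and the generating config."""

    kernels: list[KernelSpec]
    truth: pd.DataFrame                 # TRUTH_COLUMNS, frame is 1-based
    n_frames: int
    config: SimConfig
    seed: int

    @property
    def frames(self) -> FrameSequence:
        return FrameSequence(self)

    def poses_at(self, frame: int) -> list[tuple[KernelSpec, float, float, float]]:
        """Kinematic poses (spec, cx, cy, angle) of live kernels at a 1-based frame."""
        g = self.config.gravity
        t_abs = frame - 1
        poses = []
        for spec in self.kernels:
            t = t_abs - spec.release_time
            if t < 0:
                continue
            x0, y0 = spec.release_point
            vx, vy = spec.initial_velocity
            cy = y0 + vy * t + 0.5 * g * t * t
            a = spec.semi_axes[0]
            if cy - a > self.config.frame_size[1]:
                continue          # fully below the frame: kernel retired
            poses.append((spec, x0 + vx * t, cy, spec.initial_angle + spec.spin * t))
        return poses

    def _noise_pool(self) -> np.ndarray:
        """Scene-wide bank of unit-normal samples for frame augmentation."""
        pool = getattr(self, "_noise_pool_cache", None)
        if pool is None:
            w, h = self.config.frame_size
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 5023]))
            pool = rng.standard_normal(w * h + (1 << 18), dtype=np.float32)
            object.__setattr__(self, "_noise_pool_cache", pool)
        return pool

    def render(self, frame: int, augmented: bool | None = None) -> np.ndarray:
        """Rasterize one 1-based frame (deterministic per scene seed)."""
        image, _ = render_frame(self.poses_at(frame), self.config, frame=frame)
        do_aug = self.config.apply_augment if augmented is None else augmented
        if do_aug:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7919, frame]))
            image = augment(image, self.config.augment, rng,
                            noise_pool=self._noise_pool())
        return image

    def oracle_detections(self) -> pd.DataFrame:
        """Truth boxes with confidence = visibility, in detection-table form.

        Stands in for an ideal detector whose confidence degrades with
        occlusion; useful to exercise low/high-confidence association
        without any image processing.
        """
        df = self.truth.copy()
        df["conf"] = df["visibility"]
        return df[["frame", "left", "top", "width", "height", "conf"]]

    def truth_tracks(self) -> pd.DataFrame:
        """Ground-truth trajectories in MOT track-table form (exact centers)."""
        df = self.truth.copy()
        out = pd.DataFrame({
            "frame": df["frame"],
            "id": df["id"],
            "left": df["cx"] - df["width"] / 2.0,
            "top": df["cy"] - df["height"] / 2.0,
            "width": df["width"].astype(float),
            "height": df["height"].astype(float),
            "conf": 1.0,
        })
        return out


def simulate_scene(config: SimConfig) -> Scene:
    """Generate a falling-kernel scene from the configuration.

    Kernel releases follow a Poisson schedule whose rate is chosen so the
    steady-state mean number of visible kernels per frame matches
    ``density_target``; the release band cycles above-plane / at-plane /
    below-plane.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    lam = config.arrival_rate()
    g = config.gravity
    w, h = config.frame_size

    kernels: list[KernelSpec] = []
    frame = 0
    while len(kernels) < config.n_kernels:
        n_new = rng.poisson(lam)
        n_new = min(n_new, config.n_kernels - len(kernels))
        for _ in range(n_new):
            k = len(kernels)
            band = _BAND_ORDER[k % 3]
            a = rng.uniform(*config.semi_major_range)
            aspect = rng.uniform(*config.aspect_range)
            b = a / aspect
            x0 = rng.uniform(*config.release_x_range)
            y0 = config.band_release_y(band)
            vx = config.conveyor_exit_speed + rng.uniform(-config.vx_jitter, config.vx_jitter)
            vy = rng.uniform(*config.vy0_range)
            kernels.append(KernelSpec(
                id=k + 1,
                semi_axes=(a, b),
                intensity=int(rng.integers(config.intensity_range[0],
                                           config.intensity_range[1] + 1)),
                release_time=frame,
                release_point=(x0, y0),
                release_band=band,
                initial_velocity=(vx, vy),
                spin=rng.uniform(*config.spin_range),
                initial_angle=rng.uniform(0.0, math.pi),
            ))
        frame += 1

    # run until the last kernel has fully left the frame
    last_exit = 0.0
    for spec in kernels:
        a = spec.semi_axes[0]
        dist = h + a - spec.release_point[1]
        t_exit = _time_to_reach(dist, spec.initial_velocity[1], g)
        last_exit = max(last_exit, spec.release_time + t_exit)
    n_frames = int(math.ceil(last_exit)) + 2

    scene = Scene(kernels=kernels, truth=pd.DataFrame(columns=TRUTH_COLUMNS),
                  n_frames=n_frames, config=config, seed=config.seed)
    rows: list[dict] = []
    for f in range(1, n_frames + 1):
        _, records = render_frame(scene.poses_at(f), config, frame=f)
        rows.extend(records)
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    scene.truth = truth
    return scene


# ---------------------------------------------------------------------------
# persistence


def write_scene(scene: Scene, outdir: str | Path, frames: bool = True) -> Path:
    """Write a scene to disk: PNG frame sequence, MOT ground truth, config JSON.

    Ground-truth rows use the MOT convention
    ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z`` with conf=1
    and x/y/z=-1; the full truth table (centers, visibility) goes to
    ``truth.csv`` and the configuration to ``scene.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if frames:
        fdir = outdir / "frames"
        fdir.mkdir(exist_ok=True)
        for i, img in enumerate(scene.frames, start=1):
            iio.imwrite(fdir / f"frame_{i:06d}.png", img)
    with open(outdir / "gt.txt", "w") as fh:
        for r in scene.truth.itertuples(index=False):
            fh.write(f"{int(r.frame)},{int(r.id)},{r.left:.2f},{r.top:.2f},"
                     f"{r.width:.2f},{r.height:.2f},1,-1,-1,-1\n")
    scene.truth.to_csv(outdir / "truth.csv", index=False)
    with open(outdir / "scene.json", "w") as fh:
        json.dump({"config": scene.config.to_dict(), "seed": scene.seed,
                   "n_frames": scene.n_frames, "n_kernels": len(scene.kernels)},
                  fh, indent=2, default=str)
    return outdir
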