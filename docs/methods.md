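# Methods

## Problem setting

Kernels pour off a conveyor edge and fall past a fixed camera in front of
a monochromatic backdrop. The system must report how many kernels passed.
The method under test is tracking-by-detection plus a line-crossing
count: per-frame detections are linked into identities by a hierarchical
association tracker, and an identity contributes one count when its
trajectory crosses a virtual horizontal line placed across the fall path.
Everything here runs on synthetic scenes with exact ground truth, so the
tracker and counter can be evaluated at scale without hardware.

## Scene simulation

**Kinematics.** Image coordinates are raster-conventional: origin top
left, y increasing downward, so "falling" means strictly increasing y.
Each kernel is released at frame `t0` from `(x0, y0)` with velocity
`(vx, vy0)` and follows `x(t) = x0 + vx·t`, `y(t) = y0 + vy0·t + g·t²/2`.
There are no collisions; overlap is purely visual (painter's algorithm,
later-released kernels are nearer). A kernel is retired once fully below
the frame.

**Release protocol.** Kernels are released sequentially from three
vertical bands — above, at, and below the conveyor's horizontal exit
plane (offsets −40/0/+40 px), cycled per kernel — emulating the
multi-directional release used to cover the different motion states a
kernel can be in when it enters the view. Release times follow a Poisson
process whose rate is `density_target / E[visible residence]`, with the
mean residence computed from the kinematics per band, so the steady-state
mean number of kernels in view matches the configured density. Release x
is uniform across the conveyor width.

**Scale.** Genuine high-speed capture (≥1000 fps) would make trials
hundreds of thousands of frames; the simulator instead runs at a reduced
frame-rate equivalent of 120 fps chosen so that per-frame displacements
remain a few pixels — the property of high-speed footage that matters for
IoU-based tracking. Defaults map a physical rig at ~0.5 mm/px: 768×512
view, conveyor exit speed 2.2 px/frame (25 rpm on a 5 cm roller),
gravity 0.12 px/frame², kernel semi-major axes 8–12 px with aspect ratio
1.2–2.0 (maize-kernel silhouettes; the geometry is elliptical with
per-kernel spin since no true outline data exist). Release-velocity
dispersion (vx ±1.0 px/frame, vy0 ∈ [0, 2.5] px/frame) represents
tumbling off the roller edge; it also controls how often two kernels
travel as a persistent touching pair, the dominant failure mode of any
non-splitting detector (see Limitations). These values were fixed by
calibrating the synthetic regime until the stand-in detector operated at
the precision/recall a trained single-class network reaches on this kind
of footage (~0.998/0.99), then frozen.

**Rendering and truth.** Kernels are flat-shaded rotated ellipses
(intensities 120–220 over background 20, enforced margin ≥ 60)
composited nearest-last. Per kernel and frame the truth table records the
exact center, the frame-clipped bounding box, and the visibility — the
fraction of the ellipse's pixels that are inside the frame and not
covered by a nearer kernel. Truth rows exist only for kernels with at
least one visible pixel.

**Augmentation.** Per-frame photometric perturbation mirrors the
augmentations used for detector training on the real footage: brightness
shift ±10, contrast gain 0.92–1.08 about mid-gray, additive Gaussian
noise σ=3, and optional isotropic rescale (identity by default inside
scenes, since rescaling frames would desynchronize the ground truth).
Flips and rotations are deliberately excluded: mirrored or rotated falls
are physically implausible. For long scenes the per-frame noise field is
a randomly offset slice of a scene-wide pre-drawn normal pool rather than
a fresh draw; `augment()` called directly draws exact i.i.d. noise.

**Determinism.** All randomness derives from the scene seed through
named `SeedSequence` streams; frames are rendered lazily and any frame
can be regenerated identically in any access order.

## Detection

The monochrome backdrop makes classical blob detection adequate on
synthetic scenes: pixels whose absolute difference from the known
background level exceeds a threshold (default: half the
background-to-kernel intensity gap) form the foreground; 8-connected
components with area ≥ 30 px become detections. Confidence is
`min(1, area / reference_area)`: partially occluded or partially
out-of-frame kernels score low, reproducing the confidence dips a neural
detector shows under occlusion — the regime the tracker's secondary
association exists for. The reference area is the 10th percentile of the
fully visible kernel-area distribution rather than its median: with a
median reference, half of all unoccluded kernels would score below 1 and
the smallest would sit below the new-track threshold forever, starving
the tracker; with a low quantile, essentially every unoccluded kernel
saturates at 1 while meaningful occlusion still drives confidence into
the low band. Touching kernels merge into a single detection — no
splitting is attempted, which is the honest failure mode of this detector
class; the tracker is expected to survive merges.

## Tracking

Per frame: predict all live tracks, associate, update matched tracks,
manage lifecycle.

**State.** Each track carries an 8-vector (cx, cy, a = w/h, h, and their
per-frame velocities) with a constant-velocity transition. Process and
measurement noise standard deviations are proportional to box height
(weights 1/20 position, 1/160 velocity), the standard parameterization
for this filter family. Covariances are re-symmetrized after update.

**Ballistic compensation.** The cited association method assumes
constant velocity, which is exact to within noise at ≥1000 fps where
per-frame acceleration is negligible. At the 120 fps desk-scale
equivalent, a track coasting unmatched through an occlusion diverges from
the true path by g·k²/2 — about a box height after ~20 lost frames — so
the pure CV filter cannot re-acquire kernels after blob merges, a purely
scale-induced artifact. `TrackerConfig.gravity` therefore optionally adds
the known scene gravity to the vertical channel as a control input; the
standalone tracker default remains pure CV, and the pipeline fills the
flag from the simulation config.

**Association.** Detections are split at confidence thresholds 0.5
(high) and 0.1 (floor). Stage 1 matches high-confidence detections to
all live tracks by minimum-cost linear assignment on 1 − IoU, accepting
pairs with IoU ≥ 0.2; tracks are ordered by id so equal-cost solutions
resolve toward the lowest id. Stage 2 offers low-confidence detections
to the remaining unmatched active or lost tracks at the stricter gate
IoU ≥ 0.5; this is what carries identities through occlusion dips
instead of fragmenting them. Unmatched high-confidence detections with
confidence ≥ 0.6 seed new tentative tracks; low-confidence detections
never create tracks. A track is emitted once it has 2 consecutive hits,
goes lost when unmatched, and is removed after 30 lost frames. All
thresholds are the reference defaults of the association method and are
configurable. Only IoU similarity is implemented; appearance and other
motion-similarity terms are out of scope.

## Counting

The counting line spans the frame at `y0 = 0.6·H` by default (the
method needs only "a position on the fall path"; 60% leaves room for
tracks to consolidate above and still be tracked below). For each
identity the counter stores the last observed center. A count fires when
the stored height is strictly above the line (y < y0) and the current
height strictly below (y > y0), at most once per identity. Both
inequalities are strict: a sample landing exactly on y0 satisfies
neither side, and such a sample does not overwrite the stored height —
the decision defers to the next observation (otherwise an on-line sample
would absorb the crossing and the kernel would never count). If a track
vanishes above the line and reappears below with the same identity, the
stored height still triggers the count at reappearance. With
`enforce_x_extent` the x-position linearly interpolated at the crossing
instant must lie within the segment [x_a, x_b]; default off, since the
crossing condition itself uses only y.

This rule is what makes the count robust to identity churn: an identity
switch after a crossing cannot double-count (the old id is spent and the
replacement id starts below the line); a switch before the crossing
counts exactly once via the replacement id. The residual failure is an
identity that *inherits* a spent id above the line, or a merged blob
crossing as one; both require specific occlusion geometry.

## Evaluation

Detection quality: greedy confidence-descending matching to truth at
IoU ≥ 0.5 (each truth claimed once) gives TP/FP/FN; recall TP/(TP+FN),
precision TP/(TP+FP), with 0/0 defined as 0 plus a warning. AP is the
area under the precision-recall curve swept over confidence, with
all-points interpolation (right-to-left precision envelope, summed over
recall steps) — the continuous-integral form, not 11-point sampling.
There is a single class, so mAP = AP; the IoU level defaults to 0.5 and
is configurable. Counting accuracy is 1 − |predicted − true|/true as a
percentage; display values are truncated (not rounded) to one decimal —
299/300 prints as 99.6% — with the raw value always reported alongside.
Identity switches: per frame, emitted tracks are assigned to truth
objects by maximum-IoU optimal assignment (pairs under the threshold
rejected); a switch is an assignment change between a truth object's
consecutive matched frames.

## Qualification protocol and problem sizes

The batch experiment runs five independent trials of 300 kernels at the
default conditions (~5 kernels/frame, ~4800 frames per trial at the
reduced frame-rate equivalent) and reports per-trial counting accuracy
and the cumulative error of the summed batch. The acceptance script and
the test suite both run this protocol end to end (a few minutes on one
CPU); unit and property tests use smaller scenes (6–80 kernels, a
384×320 view with the same physics) and constructed fixtures. Oracles
are independent re-implementations: brute-force permutation enumeration
for assignment optimality and detection matching, pixel-count rasters
for visibility, a y-sequence scan for the crossing count, and hand
arithmetic for the metric formulas.

## What the simulator does and does not show

Passing these tests shows the tracker and counter are correct and robust
under ballistic motion, occlusion-driven confidence dips, blob merges,
and identity churn at the configured densities. It does not exercise:
real kernel texture and lighting (flat-shaded ellipses only), motion
blur (approximated only by noise/contrast perturbation), 3D depth
(touching in projection always merges here, whereas a trained detector
resolves most such pairs — the synthetic geometry is calibrated so
persistent co-moving pairs are about as rare as deep occlusion is for
that detector), rebounds or kernel-kernel collisions, and camera
artifacts. Counting failures that remain in simulation are almost
exclusively pairs that touch for longer than the track-removal horizon
while straddling the counting line.

## Known limitations

- The blob detector requires a known, roughly uniform background level;
  it is a stand-in for a trained detector, not a general-purpose one.
- Merged detections are never split; sustained merges (> 30 frames)
  spanning the counting line undercount by one per pair.
- mAP is single-class by construction.
- The constant-acceleration option assumes gravity is known and vertical;
  it is not an estimator.
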