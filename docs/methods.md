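# Methods

This note documents the models, conventions and numerical choices behind
`pigmotion`, and what the synthetic test bed does and does not establish
about real footage.

## Geometry conventions

Boxes are `(left, top, width, height)` in 0-based image coordinates with
half-open pixel coverage `[x, x+w) × [y, y+h)` — the MOTChallenge CSV
semantics.  Boxes stay real-valued through the whole pipeline (Kalman
prediction produces sub-pixel boxes); discretization happens only where a
pixel set is needed, by rounding the left/top edge to the nearest grid
line and taking `round(w) × round(h)` pixels.  An interior box therefore
covers exactly `round(w)·round(h)` pixels, and the Eq.-style normalizer
`h×w` of the mean-in-box-flow estimator is implemented as this discrete
pixel count, so partially out-of-frame boxes average only over their
visible pixels instead of being biased toward zero.  Zero-area boxes have
IoU 0 against everything, including themselves, which keeps them out of
every association.

## Tracker

One step of the two-stage association: (i) detections below 0.1 are
discarded, the rest split at τ = 0.5 into high/low confidence; (ii) every
live track — lost ones included — is propagated one frame by its Kalman
filter; (iii) high-confidence detections are matched to predicted boxes by
a Hungarian assignment on 1 − IoU, gated at 0.5; (iv) low-confidence
detections are matched to the remaining tracks the same way; (v) matched
tracks are corrected and reactivated, unmatched low-confidence detections
are dropped as background, unmatched tracks become lost and are removed
after 30 missed frames, unmatched high-confidence detections start new
tracks immediately (no probation), and the live-track count is capped at
100, evicting the longest-lost first (ties to the smaller id).  Greedy NMS
at IoU 0.5 runs on the raw detections before splitting.  All thresholds
are configurable (`TrackerConfig`); the defaults above are the documented
operating point.  The score split τ deserves note: only the detection
floor (0.1) and matching/NMS thresholds (0.5) have stated values in the
upstream literature for this setting, so τ defaults to 0.5 and is exposed
as a flag rather than hidden.

The Kalman filter is the SORT-family convention: state
(cx, cy, a, h, ċx, ċy, ȧ, ḣ) with a = w/h, constant-velocity transition,
measurement (cx, cy, a, h), and noise standard deviations proportional to
box height (1/20 position, 1/160 velocity; aspect terms fixed at 1e-2 /
1e-5 / 1e-1 for initiation, process and measurement).  Height scaling
keeps the filter equally responsive for near and far (small and large)
animals.  The per-frame box stored in a track's history is the matched
detection's box, not the Kalman posterior; the filter state only drives
prediction.  This makes evaluation reflect the detections actually
consumed, and makes noise-free closure exact.

Two deliberate readings of ambiguous points: lost tracks keep being
predicted and may match in *either* association stage (the alternative —
restricting the second stage to just-unmatched active tracks — fragments
occluded identities), and assignment ties break lexicographically by
(track index, detection index) for reproducibility.

## Optical flow

The estimator solves brightness constancy by coarse-to-fine pyramidal
iterative Lucas–Kanade: Gaussian pyramid (scale 0.5, 3 levels, levels
smaller than the window are dropped), and per level 3 warp/solve
iterations.  Each iteration warps frame t+1 toward frame t by the current
flow (bilinear, replicate border), forms spatial gradients as the mean of
both frames' central differences and the temporal difference, aggregates
the normal equations with a Gaussian window (σ = window/5, window 15 px),
and solves the 2×2 system per pixel with a Tikhonov regularizer of
1e-4 × mean gradient energy — textureless regions then return finite,
near-zero flow instead of NaNs.  Per-iteration increments are clipped to
the window size to prevent blow-ups at pathological pixels.  Intensities
are min–max normalized first so the regularizer scale is
image-independent.

Convention: forward flow, `F` at pixel (x, y) of frame t is that pixel's
displacement into frame t+1, in pixels/frame.  Border estimates use
replicate padding and are the least reliable; accuracy properties are
asserted on the interior (margin ≈ window).  On 128×128 band-limited noise
textures the median interior endpoint error for integer shifts up to 4 px
is below 0.01 px.

Flow is stored as float32 (the Middlebury `.flo` layout: magic 202021.25,
int32 width/height, interleaved row-major float32), which bounds
"exactness" everywhere downstream at single precision.  Any external flow
producer can replace the built-in estimator by supplying per-pair `.flo`
files; the movement module only sees `FlowField` objects.

## Movement estimators

Per identity and frame pair (t, t+1), anchored at the track's box at frame
t (forward flow lives on frame t):

* `bbox_center` — Euclidean distance between consecutive box centers.
  Under pure center jitter N(0, σ²I₂) per frame the consecutive-frame
  difference is N(0, 2σ²I₂), so the expected phantom movement is σ√π per
  frame (≈ 3.5 px at σ = 2) even for a motionless animal.
* `rep_point` — flow magnitude at a representative point initialized at
  the center of the track's first box and advanced by the local flow each
  frame (clipped to the field).  Follows one body point; ignores motion of
  other parts.
* `box_mean_flow` (default) — mean flow magnitude over the box's pixel
  set.  Averaging over the whole box includes background pixels: an object
  of pixel area A moving rigidly at speed s inside a box of area P reads
  s·A/P exactly under ground-truth flow (the fill-factor law, verified in
  tests).  No foreground mask is applied — the estimator is implemented
  literally, and the fill-factor law documents the consequence.

Tracks with gaps (lost, later re-found) contribute no records during the
gap; omission is auditable where interpolation would not be.  Cumulative
series are running sums per identity.

## Evaluation

CLEAR counting follows the MOTChallenge convention: correspondences kept
from the previous frame while still within the IoU gate (0.5), the
remainder matched by a gated Hungarian assignment that maximizes matches
first (infeasible pairs carry a large constant cost), identity-switch
memory persisting across gaps.  MOTA = 100·(1 − (CFN+CFP+IDSW)/GT).
Identity metrics solve one global bijection between ground-truth and
predicted identities minimizing total mismatched frame-entries, via an
assignment problem with unmatched-identity dummies;
IDF1 = 100·2·IDTP/(2·IDTP+IDFP+IDFN).  Both families use gate 0.5.
Percentages print at one decimal; raw doubles are preserved in machine
output.  HOTA, MOTP and MT/ML statistics are out of scope.

## Synthetic scenes

The generator emulates a fixed overhead pen camera: a static band-limited
noise floor (smoothed white noise — deliberately rich in gradients, since
classical flow needs texture) with 4–8 textured rectangles/ellipses,
rendered at sub-pixel positions by bilinear splatting.  Default
populations place one animal per grid territory (one always stationary,
the rest drifting at 0.5–3 px/frame with border bouncing), so distinct
animals' boxes never overlap; `crossing_objects` adds a smaller animal
shuttling beneath a larger one to create genuine occlusion (visible
fraction below one half) while keeping inter-box IoU under the NMS and
matching gates.  Occlusion resolves by draw order (painter's algorithm);
ground-truth boxes stay amodal while the visible fraction drives the
detector-score drop.  Ground-truth flow assigns each object pixel its
object's displacement, occluded pixels the occluder's displacement, and
background exactly (0, 0).

The detection-noise model covers the failure modes that motivate the flow
estimators: Gaussian center/size jitter, missed boxes, a score drop to 0.3
when the visible fraction falls below one half (base score 0.9), and
Poisson spurious low-score boxes.  The jitter default used in the
headline contrast, σ = 2 px, is chosen to make the center-vs-flow contrast
unambiguous; it is not calibrated to any particular detector.

What passing on this test bed does *not* show: robustness to lighting
changes, deforming bodies, camera motion, motion blur, or detector error
statistics beyond the Gaussian/Poisson model — brightness constancy holds
by construction here, which is exactly why real deployments may prefer
precomputed flow from a stronger estimator via the `.flo` backend.

## Problem sizes

Tests and the acceptance script run on scaled-down scenes chosen to be
fully representative of the mechanisms: 128–320 px frames, 4–7 objects,
40–200 frames, 100 frame pairs for the movement contrasts, 500 random
association instances and 50 random evaluation scenarios against
enumeration oracles.  The full-scale 640×640/1800-frame geometry is the
generator default and exercised via its arithmetic, not re-rendered in
full during tests.
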