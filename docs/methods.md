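# Methods

This note records the model, the procedure, the parameter choices, and the
numerical conventions implemented in `orchardtrack`, including every place
where the implementation had to pick one of several defensible readings.

## 1. Problem

Estimate the number of apples on a row of trees from video taken by a camera
driven along the row, attribute the count to GPS positions, and place harvest
containers along the row so that no container exceeds its capacity and (optionally)
no stretch of row is farther than a trigger distance from a container.

The object detector and appearance-feature CNN are upstream components and are
represented only by plug-in protocols (`Detector`, `FeatureExtractor`) and a
CSV dialect; everything downstream of the detector is implemented here.

## 2. Detection correction

A detection is a box `(cx, cy, w, h)` with a confidence score. Two filters run
before tracking:

- **Confidence:** keep `confidence ≥ 0.4`.
- **Size:** discard a box only if *both* `w < 30` and `h < 30` px (strict
  inequality; boxes at the threshold are kept). Small boxes come from fruit in
  the next tree row and would otherwise inflate the count. The conjunctive
  reading is the default because a genuinely distant fruit is small in both
  dimensions, while a partially occluded near fruit can be thin in one;
  `DetectionFilterConfig(require_both_dims_small=False)` selects the
  disjunctive reading.

## 3. Tracking and counting

### State and motion

Each track holds an 8-dim state `(x, y, a, h, ẋ, ẏ, ȧ, ḣ)` — box center,
aspect ratio `a = w/h`, height, and velocities — with a constant-velocity
linear Kalman filter. Noise standard deviations scale with box height:
position-like terms `h/20`, velocity-like terms `h/160`; a new track's
velocity variance is initialized at 10× its position variance. This is the
standard DeepSORT parameterization; scaling with `h` makes the filter
scale-invariant across near and far fruit.

### Association

The primary association stage uses **appearance only** (no Mahalanobis/motion
gate): the cost between track `i` and detection `j` is the minimum cosine
distance between the detection's feature vector and any vector in the track's
gallery of past matched features (bounded at the 100 most recent). Costs above
the gate 0.15 are replaced by a large sentinel (`1e5`); the assignment is
solved exactly with the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment` on a square, sentinel-padded matrix),
and matches whose cost is the sentinel are discarded. Cosine distance is
`1 − 〈u, v〉/(‖u‖‖v‖)`; zero vectors are rejected.

Unmatched tracks and unmatched detections then enter an **IoU fallback**:
greedy matching by greatest intersection-over-union between the track's
Kalman-predicted box and the detection box, accepting pairs with `IoU ≥ 0.3`
(ties broken toward the lower track id). This recovers matches when appearance
is degraded (blur, occlusion flanks).

### Lifecycle and counting

- New tracks start **tentative** with id numbers from 1.
- A track is **confirmed** after 3 matched frames; the yield count increments
  exactly once, at confirmation. Confirmation events are logged per frame for
  the geospatial stage.
- A tentative track missing in a frame is deleted immediately; a confirmed
  track is deleted after 30 consecutive frames without a match.
- **Duplicate-spawn suppression:** a detection that overlaps an
  already-claimed detection at `IoU ≥ 0.9` does not spawn a new track. This
  stands in for detector-side non-maximum suppression; without it, exact
  duplicate boxes (which real detectors do emit) would each spawn a track and
  inflate the count.

The per-frame step order is: predict → appearance association → IoU fallback →
update matched tracks → spawn (with suppression) → confirm/delete → age
bookkeeping (ages increment only for tracks that existed before the frame).

## 4. Geospatial annotation

With GPS period `t` seconds and video rate `f` fps, each GPS fix covers
`W = round(t·f)` frames; `t·f` must be integral to within 1e-9, otherwise the
configuration is rejected. Frame window `[kW, (k+1)W)` is attributed to fix
`k`; a trailing partial window is still emitted so confirmation events are
conserved. Distances use the haversine formula with Earth radius
6,371,000 m, converted to feet at 3.28084 ft/m. Geo-counts are written as
`Lat,Lng,Count` CSV and as a plain-dict GeoJSON `FeatureCollection`
(coordinates in `[lng, lat]` order).

## 5. Container placement

Given geo-counts, container capacity `m`, apple weight `w` (capacity in
apples is `m/w`) and optional trigger distance `d_max` ft, a single forward
scan places containers:

- Apples accumulate into the open container in row order; when adding a
  point would overflow, the container is closed at that point, taking a
  fractional share if splitting is allowed (default) or raising an error if not.
- **Distance trigger:** before a point's apples are added, if the haversine
  distance from the previous placement to this point reaches `d_max`, the open
  container is closed *at this point without taking its apples*. The literal
  invariant "consecutive placements are ≤ d_max apart" is unattainable at GPS
  granularity (two adjacent fixes can already be farther apart than `d_max`),
  so `verify_plan` audits the attainable version: every geo-point strictly
  between consecutive placements must lie within `d_max` of the earlier
  placement, i.e. the trigger fired at the first opportunity.
- The final container is placed at the last geo-point.

Without a distance trigger the greedy scan is provably optimal: it emits
exactly `⌈total·w/m⌉` containers (every container but the last is full), which
is the counting lower bound. Tests check this against the bound on 500 random
instances and against an exhaustive oracle on small instances with the trigger
active. Utilization is `assigned/(m/w) × 100`, printed with one decimal and
trailing zeros trimmed (`77%`, `76.7%`, `53%`).

Reference arithmetic: a row totaling 3530 apples fills 12 containers of
capacity 300 (11 full + one with 230 apples, 76.7%≈77%) and 4 containers of
capacity 1000 (final utilization 53%).

## 6. Evaluation

`L1 = |predicted − GT|`; `accuracy = (GT − L1)/GT × 100`, taken literally (it
can go negative when the error exceeds the ground truth). `GT = 0` is
rejected.

## 7. Synthetic scene generator

The simulator emulates a camera panning horizontally along a fruit wall at 16
px/frame over a 1920×1080 viewport, 240 frames at 30 fps by default. Fruits
are placed in a world strip so each is fully visible for at least 10 frames;
box sizes are Normal(45, 6) px clipped at ≥ 32. Per frame, each visible fruit
emits a detection with 1 px center jitter, a confidence drawn from
[0.75, 0.99], and an appearance vector derived from the fruit's latent
identity (uniform on the unit sphere, dim 512).

Degradations, all seeded per-fruit via `numpy.random.SeedSequence.spawn` so
scenes are reproducible and fruits independent:

- **Feature noise:** the observed feature is
  `normalize(latent + N(0, σ²/d · I))` with σ = 0.05. σ is interpreted as the
  *expected noise norm*, not the per-component standard deviation — at
  d = 512 a per-component σ of 0.05 would give noise of norm ≈ 1.13,
  destroying all appearance matches under the 0.15 gate; the norm convention
  keeps the noise scale meaningful independent of feature dimension.
- **Dropout:** each detection is dropped with probability 0.05.
- **Occlusion:** with probability 0.3 a fruit gets one occlusion window of
  3–8 frames with no detections, flanked by "blurred" frames with confidence
  in [0.4, 0.7] and feature noise ×8.
- **Clutter:** 5 small background boxes (10–29 px) per scene, below the size
  filter, with their own latents.

The generator does **not** emulate: camera shake/rotation, perspective or
scale change with depth, fruit motion, lighting drift, or detector
localization bias. `simulate_gps_track` generates fixes along a bearing at a
fixed spacing (spherical destination formula); zero spacing repeats the start
fix exactly.

## 8. Test problem sizes

Scene sizes in the test suite (10–100 fruits, 100–240 frames) were chosen to
keep the full suite under ~2 minutes while exercising multi-fruit occlusion
and clutter interactions; they are this package's own choices, not an
external benchmark. Noiseless scenes (σ = 0, no dropout/occlusion/clutter)
must be counted exactly; default-noise scenes are required to land within 10%
of truth in at least 18 of 20 seeds.

## 9. Limitations

- Appearance gating at 0.15 presumes features resembling unit-sphere
  embeddings; poorly normalized features will route everything through the
  IoU fallback.
- The greedy placement optimizes container count under scan-order semantics;
  it does not re-order pickup or balance loads.
- Accuracy as defined is a scalar count metric; it does not detect
  compensating double-counts and misses.
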