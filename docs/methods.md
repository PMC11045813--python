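# Methods

## Problem setting

An underwater camera inside a demersal trawl records the catch drifting
toward the codend at 1280×720 pixels, 60 frames per second. A per-frame
object detector (not part of this package) emits confidence-scored bounding
boxes for Norway lobsters; `trawlcount` turns those boxes into a catch
count and evaluates how well the count matches ground truth. The package is
deliberately detector-agnostic: its primary input is a replayed detection
stream in a MOT-Challenge-style CSV (`frame,id,x,y,w,h,conf`, 1-based frame
indices on disk, 0-based in memory), and any external detector can be
plugged in through `AdapterSource` under the same one-frame-at-a-time
(batch of 1) contract.

## Tracking

Tracking is classic SORT. Each track owns a linear Kalman filter over
`[u, v, s, r, du, dv, ds]` — box center, area, aspect ratio, and the
per-step velocities of the first three; the aspect ratio is modelled as
constant. The transition is constant-velocity; the observation is
`[u, v, s, r]`. Noise matrices follow the SORT reference implementation
(measurement `diag(1, 1, 10, 10)`, process `diag(1,…)` with the velocity
block and area-velocity damped ×0.01, initial covariance `10·I` with the
unobservable velocity block ×1000); both are exposed as scale factors in
`TrackerConfig`, and driving them toward zero turns the filter into an
asymptotically exact least-squares line fit — which the tests exploit as a
closed-form oracle.

Per processed frame the tracker predicts every live track, assigns
detections to predictions by maximum total IoU (Hungarian algorithm via
`scipy.optimize.linear_sum_assignment`), updates matched tracks, births
tracks from unmatched detections, and retires tracks not updated for more
than `max_age` steps. Two numerical details:

- IoU entries below `iou_min` are zeroed *before* solving the assignment.
  Filtering sub-threshold pairs after a plain Hungarian solve — the common
  shortcut — is not optimal for the thresholded objective; zeroing first
  is, and the brute-force permutation oracle in the tests confirms it.
- If a predicted step would drive the box area non-positive, the area
  velocity is clamped to zero so the state always converts back to a valid
  box (minimum area 1 px²).

Defaults: `iou_min = 0.3`, `min_hits = 3` (a track must be updated three
times before it is confirmed and eligible for counting), `max_age = 3`
(raised from SORT's 1 to ride out detector dropouts and skipped frames).
The tracker's clock ticks once per *processed* frame; skipped frames are
invisible to it. The alternative — one predict per elapsed native frame —
is available as `predict_through_skips` for detectors whose dropout
behaviour warrants it.

## Counting

A horizontal counting line sits at `line_fraction` (default 4/5) of the
frame height, measured from the top in y-down coordinates — near the bottom
of the frame, where catch exits toward the codend. A confirmed track is
accepted as a catch the first time any enabled condition holds, and never
again:

1. **bottom_cross** — the box bottom moves from above the line to at-or-
   below it between two consecutive observations of the track;
2. **center_cross** — same for the box center;
3. **tall_box** — the box height strictly exceeds `height_fraction`
   (default 2/3) of the frame height, regardless of position. This catches
   individuals so close to the lens that their box never cleanly crosses.

"Crossing" requires an observed above→below transition, inclusive on the
below side. Two genuinely open design points are resolved as explicit,
configurable defaults:

- A track whose *first-ever* observation is already past the line fires no
  crossing condition (no transition was observed). Enable
  `count_on_first_sight_below` to count such tracks.
- Conditions are evaluated on associated detection boxes only; a coasting
  track's Kalman-predicted box does not count (`count_on_predicted`),
  avoiding ghost counts from tracks that drift on after their object is
  gone.

Because the bottom of a box is always below its center, condition i fires
at or before condition ii on any descending track; animals hovering above
the line, or swimming back against the flow, are never counted — the
crossing requirement handles direction implicitly.

## Frame-skipping schedulers

Five modes, all anchored at frame 0 processed:

| mode | pattern | processed fraction |
|------|---------|--------------------|
| none | P P P … | 1 |
| fs1  | P P S   | 2/3 |
| fs2  | P S     | 1/2 |
| fs3  | P S S   | 1/3 |
| adaptive | content-driven | between 1/3 and 1 |

The adaptive rule: after a processed frame with no detections, skip the
next two frames and process the third; after a processed frame *with*
detections, process the next two frames. Commitments are kept as a
forced-process counter, max-merged at 2 on every detection-bearing frame —
so a later empty frame cannot cancel an outstanding commitment, and on an
all-empty stream the policy is exactly fs3 while on a saturated stream it
converges to processing every frame.

Effective throughput of a processed frame is `(1 + k) / t`, where `t` is
its measured processing time and `k` the number of frames skipped
immediately before it: a 50 ms frame is 20 FPS raw, 40 FPS under fs2, 60
FPS after two skips. Min/mean/max over the run are reported, and a run is
flagged *real-time* when the mean is at or above the native frame rate.

## Evaluation

Counted tracks are matched one-to-one to ground-truth trajectories:
a counted track is a candidate for a ground-truth object if on at least one
shared frame their boxes overlap with IoU ≥ 0.5 (configurable); candidates
commit greedily in descending order of best single-frame overlap. Matched
counts are TP, unmatched counts FP, never-matched ground-truth objects FN,
so TP + FN = GT by construction. This rule replaces a manual labelling
protocol that cannot be automated verbatim; it is explicit and
deterministic instead. Correct count rate = 100·TP/GT and
F = TP/(TP + 0.5(FP+FN)) (algebraically the harmonic mean of precision and
recall); both undefined — an error, not a silent 0 — when their
denominators vanish. Reports round rates and F-scores to two decimals.

FN here includes both objects that were never detected and objects that
were detected but whose tracks never satisfied a count condition; the
distinction is not recoverable from counts alone.

## Synthetic scenes

`generate_scene` emulates the statistical structure of in-trawl footage:
objects arrive as a per-frame Poisson process (default rate 0.0727
objects/s — about one lobster every 14 s, the sparse regime of real hauls;
a fixed `n_objects` mode exists for tests needing exact counts), enter at
the top edge at a uniform horizontal position, drift downward at
Gaussian-perturbed speed (default 4 ± 0.4 px/frame, i.e. ~240 px/s, about
three seconds to cross the frame; negative steps are clamped so
trajectories are monotone in y), grow slowly in apparent size (0.1 %/frame)
as they approach the lens, and exit at the bottom. The emulated detector
adds Gaussian localization noise (default 2 px) to position and size, drops
detections with probability 0.1, draws confidences from a clipped normal
(0.8 ± 0.1), and injects Poisson(0.01/frame) spurious boxes uniformly in
the frame. Everything derives from one `numpy.random.default_rng(seed)`,
so a scene is byte-reproducible from its config. The scene's ground-truth
count is the number of objects whose box bottom reaches the counting line
during the video.

What the generator does *not* model — and hence what passing tests do not
show about real footage: temporal clustering of arrivals (real catch comes
in bursts), occlusion and overlap between individuals, non-lobster catch
items, appearance variation, turbidity, and camera motion. An optional
`render_frame` draws targets as bright ellipses on a dark background so a
classical blob detector can exercise the adapter path end-to-end; no test
requires rendering.

## Problem sizes used in the checked examples

The test suite and acceptance script run entirely on synthetic scenes:
30-second, 1800-frame scenes with 3–8 objects (20 zero-noise seeds and 50
moderate-noise seeds), 6000-frame schedule masks, 500 random assignment
matrices up to 5×5 against a brute-force permutation oracle, and 1000
random box pairs against a rasterized IoU oracle. These sizes make the
whole suite run in well under a minute while leaving the statistical checks
(Poisson arrival rates, mean count rates) adequately powered.

## Known limitations

- SORT hyperparameters for the original field deployment are not public;
  per-video track counts from real hauls are not claimed to be
  reproducible, only the formula-level quantities and the pipeline's
  properties.
- The tracker has no appearance model; two lobsters crossing paths can
  swap identities. At realistic densities (< 0.1 objects/s) this is rare.
- Wall-clock FPS figures on replayed detections measure the tracker alone
  and are orders of magnitude above any detector-in-the-loop deployment;
  the real-time flag is only meaningful with a real detector attached.
- Frame tallies of a live deployment can disagree slightly with
  duration × FPS (container timestamps, dropped frames); the scheduler
  here is exact by construction.
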