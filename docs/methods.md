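# Methods

`paniclepheno` models the analysis chain of a fixed nadir camera monitoring a
small paddy plot through the heading–flowering stage: a detector proposes one
bounding box per rice panicle per frame, a classifier scores each box for
*vigorous flowering* (abundant open spikelets with extruded anthers), and the
analysis turns those per-frame detections into plot-level and single-panicle
phenology. The detector/classifier front end itself is out of scope; the
package simulates its output, which makes every downstream stage exactly
testable against a known latent state.

## The synthetic scene

The latent state of a plot-season (`synthetic_scene.SceneConfig`,
`simulate_population`) is a population of `n_panicles` panicles:

- **Emergence.** Each panicle emerges (heads) on a day drawn from a normal
  distribution `N(emergence_mean_dat, emergence_sd)` truncated to the study
  window (default DAT 58–71) and rounded to a whole day. The cumulative
  emerged count therefore follows a logistic-like curve that plateaus at the
  population size — the shape on which stable-number and heading-date
  estimation rely.
- **Flowering window.** Flowering starts `lag` days after emergence
  (`lag = max(0, round(N(flowering_lag_mean, flowering_lag_sd)))`) and lasts
  `max(1, round(N(flowering_days_mean, flowering_days_sd)))` consecutive
  days.
- **Daily vigorous interval.** On each flowering day the panicle shows one
  contiguous vigorous interval. Its *centre* is drawn
  `N(vft_center_mean, vft_center_sd)` (minutes from 08:00) and its *width*
  `N(dbe_mean, dbe_sd)`, floored at one observation quantum (10 min): a
  flowering day whose vigorous span is shorter than a single observation
  interval would be unobservable in principle and would contradict the
  generator's own flowering-day ground truth. Interval endpoints are
  quantised to the 10-minute grid of the dense protocol's midday core,
  because flowering-state transitions are only defined at the cadence at
  which the state is observed; without this quantisation the sampling phase
  would bias recovered start times by about +5 min and daily spans by about
  −10 min for any downstream estimator, an artefact of the simulation rather
  than a property of the method.
- **Weather suppression.** Days listed in `suppressed_days` simply lose their
  intervals (rain/cloud suppresses anthesis); the N150 calibration carries
  the observed suppressed days DAT 63–64.
- **Geometry.** Base boxes sit on a planting-grid layout (spacing in cm at
  71 px/cm) with a small random offset, sizes near 90×70 px (annotation
  floor 20×20 px), and grow slowly and linearly with days since emergence
  (5 %/day, capped at 1.4×). The grid is a stand-in: the source experiment
  does not state how many panicles each hill contributes within the camera
  footprint. Boxes are static within a day, which matches the fixed-platform
  geometry but idealises wind motion (see *Limitations*).

Rendering (`render_detections`) adds the detector/classifier noise: each
emerged panicle is detected per frame with probability `detect_recall` and
jittered box coordinates; false positives arrive Poisson per frame
(`detect_precision_fp_rate`) with uniform positions and realistic sizes; the
vigorous-class score lands on the correct side of 0.5 exactly when the frame
minute is inside the day's interval, flipped with probability
`class_error_rate`. All draws come from a single seeded generator, so a
(config, schedule, seed) triple reproduces a stream byte-for-byte.

**Sampling schedules.** Two daily protocols are modelled: `hourly`, 9 frames
on the hour 08:00–16:00 (counting/heading work), and `dense`, 41 frames
(15-min cadence on the 08:00–10:00 and 14:00–16:00 shoulders, 10-min cadence
over midday) for tracking and flowering-time work. The original
acquisition's random within-hour frame choice is replaced by the nominal
grid: the analyses depend only on frames per day, and nominal times make
runs reproducible.

**Calibrations.** Packaged per-treatment configs (`CALIBRATIONS`) carry the
field trial's plateau counts (N150 23, N300 31, N270 28, N240 27 — the
published fractional stable numbers arise from averaging over sub-images,
which the simulator does not reproduce) and the published single-panicle
flowering statistics of the 2020 treatments (e.g. N300: FDs 4.40 ± 0.70
days, VFT_p 211 ± 27 min, daily DBE 93.7 ± 38.4 min). The published VFT_p is
the *start* of the daily interval while the generator draws the centre, so
calibrations set `vft_center_mean = VFT_p + DBE/2`. N150 has no published
single-panicle row and uses the across-treatment means. Detection noise
defaults (recall 0.86, ≈2.5 false positives per frame, 4.5 % class error,
3 px jitter) sit near the published detector validation metrics (precision
0.904, recall 0.861). Two published inconsistencies are worth knowing:
mean FDAT for N300 (61.20) precedes the observed 50 % heading day (62), which
cannot hold jointly with `fdat ≥ emergence`, so the calibration keeps the
emergence centre and a small non-negative lag; and the N240 DAT 62 group-VFT
row prints manual 11:00 / estimated 11:10 with error 0 — the error column is
kept verbatim in `reference.py` so the published column means
(6.67/8.33/6.67 min) are reproducible, and the recomputed N240 mean from the
times (8.33 min) differs.

## Tracking

`tracking.track_stream` is tracking-by-detection, per frame: confidence
filter (default 0.25, the detector's own threshold), greedy NMS (IoU gate
0.7), constant-velocity Kalman prediction per live track, Hungarian
assignment on the `1 − IoU` cost between predicted and detected boxes with
an association gate `max_iou_distance = 0.7`, measurement update of matched
tracks, and lifecycle bookkeeping (tentative tracks die on their first miss;
confirmed tracks survive up to `max_age = 5` consecutive misses by coasting
on the prediction; `n_init = 1` confirms on first detection). Track IDs are
assigned in creation order and never reused.

The one deliberate simplification relative to the full appearance-based
tracker this emulates: re-identification embeddings, cascade matching and
Mahalanobis gating are replaced by the IoU-only cost with a single Hungarian
pass. The appearance network is a trained artifact unavailable here, and on
fixed-camera scenes with grid-spaced, slow-growing targets spatial overlap
is the signal that matters. The Kalman state is `(cx, cy, w, h, vcx, vcy)`
with position/velocity noise proportional to box size (no published noise
values exist for this rig; these are the standard conventions). Hungarian
ties are broken toward the lexicographically smallest assignment by an
epsilon perturbation, for determinism.

**Tracking accuracy** follows the field definition: the fraction of panicles
visible in the day's first frame that a *single* track covers (IoU ≥ 0.5
against the true box) in every sampled frame of the day. Coasted (predicted)
frames count as coverage — a track that bridges a short detector dropout has
not lost the identity — but an ID switch, late birth or early death excludes
the panicle. Requiring a matched detection in every one of 41 frames would
drive the statistic to ≈`recall^41` ≈ 0 at realistic recall, which is not
what the daily-accuracy statistic measures. At the packaged noise
calibrations the simulated accuracies land at ≈0.75–0.88, the range reported
for the real scenes. Cross-day tracking is not attempted (overnight
displacement defeats overlap association, as observed in the field study);
cross-day identity comes from simulator provenance or an explicit ID map,
standing in for manual visual inspection.

## Population traits

- `pn(day)` — mean post-NMS detection count over the day's frames;
  per-day medians come from the same counts.
- **Stable panicle number** — mean `pn` over the plateau, where the plateau
  starts at the first day reaching 95 % of the maximum daily mean (the
  plateau is identified visually in field practice; 95 % is exposed as
  `plateau_frac`).
- **Heading dates** — first day whose mean *and* median counts both reach
  10 % / 50 % / 80 % of the stable number (initial / heading / full heading).
  "Exceed" is implemented as ≥: with integer counts the distinction only
  matters on exact ties, and ≥ reproduces the published outcomes. Heading
  duration is reported as `full − initial` (a difference, not an inclusive
  span, matching how the quantity is discussed qualitatively).
- `fn(day)` — maximum per-frame count of vigorous boxes
  (`vf_prob > 0.5`; the threshold stands in for the two-class argmax and is
  exposed). **VFT_g** is the frame minute of the day's peak `fn`-by-frame,
  earliest frame on ties. **Flowering duration** is inclusive:
  first-to-last flowering day, `end − start + 1` days. The cumulative
  flowering curve is the running sum of per-frame vigorous counts.

## Single-panicle traits

From each joined panicle's per-day flag series (vigorous flag per matched
frame), with persistence parameter `k` (default 2):

- a day is a **flowering day** iff it contains a run of ≥ k consecutive
  vigorous frames ("continuously appearing"; k=2 is 15–25 min of persistence
  on the dense schedule — the field definition names continuity but no
  window, so k is exposed);
- **FDAT** = earliest flowering day, **FDs** = number of flowering days —
  the same day set defines VFT_p and daily DBE, keeping the four traits
  jointly consistent;
- **VFT_p(day)** = first minute of the qualifying run; **daily DBE(day)** =
  last vigorous minute − run start (a single trailing vigorous frame counts
  as the end; a day with only isolated vigorous frames contributes 0);
  **total DBE** = Σ daily DBE.

Treatment summaries report mean ± sd per trait with compact-letter
significance groups from all-pairs Tukey HSD at α = 0.05 (the field table
names no procedure; Tukey + insert-absorb letters is the standard choice).

## Evaluation metrics

Greedy confidence-descending matching at IoU ≥ 0.5 (the detection-benchmark
convention) yields TP/FP/FN for precision, recall, F1 (0 when TP = 0); AP50
integrates the all-point interpolated precision envelope of the pooled
ranked detections — a 101-point interpolation would differ by at most the
interpolation granularity. Counting agreement is `R² = 1 − SS_res/SS_tot`
(negative allowed; undefined for constant labels) and
`RMSE = sqrt(mean((c_i − ĉ_i)²))`. Classification adds
`(TP+TN)/(TP+TN+FP+FN)`. Heading-date error is the per-treatment absolute
day difference and its mean; group-VFT error the per-day absolute minute
difference and its mean.

## Problem sizes and numerical choices

The test suite and the acceptance script run plot-scale scenes: 23–31
panicles, 14 days, 9 or 41 frames/day; per-panicle recovery statistics pool
8–16 replicate plots (≈250–500 panicles), at which scale the Monte-Carlo
standard error of mean FDs is ≈0.03–0.04 days. All randomness flows from
`numpy.random.default_rng` seeds; identical seeds give byte-identical
streams and manifests. Degenerate inputs are rejected with named errors
(zero-variance counts, empty frames, empty schedules, all-zero count
curves), and tie-breaks (NMS confidence ties, Hungarian cost ties, VFT peak
ties) are deterministic and documented at the function level.

## What passing tests do and do not show

The simulator reproduces the statistical structure the analysis assumes —
logistic-like emergence, plateaued counts, midday-peaked contiguous
vigorous intervals, weather-suppressed days, detector noise near the
published validation metrics — but not real imagery: no occlusion between
neighbouring panicles, no wind-driven within-day box motion, no duckweed or
water-reflection false-positive structure, no boundary truncation of boxes
at sub-image edges. Published image-dependent results (detection
precision/recall themselves, counting R²/RMSE, the specific per-day
tracking accuracies) are therefore *calibration anchors*, not reproduction
targets: passing tests show the analysis pipeline is correct and
internally consistent under the stated generative model, and that its
estimators recover that model's parameters; they do not certify performance
on real scenes.
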