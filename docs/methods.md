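# Methods

This note documents the models and procedures implemented in `sowmotion`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Signal model and features

The sensor measures s(t) ∈ ℝ³ in g₀ units, clipped to ±8 g₀ (saturation),
nominally at 100 Hz, with axes x craniocaudal, y mediolateral, z
dorsoventral for a sensor mounted on the sow's hind end.  The static
(gravity) component is estimated per axis with a first-order recursive
filter

    gᵢ(t) = α·sᵢ(t) + (1 − α)·gᵢ(t − 1),

a convex combination, so the estimate is bounded by the input and constant
input is a fixed point.  **α defaults to 0.01** at 100 Hz (≈1.6 s time
constant): slow enough to suppress gait and body sway, fast enough to track
posture changes that take several seconds.  A `literal_sign` flag exposes
the variant with a minus before (1 − α), which oscillates for constant
input; it exists only for auditability and is never the default.  The
initial state defaults to the first sample, so a stationary animal produces
no start-up transient.

Frames are consecutive, non-overlapping windows of 2 s (200 samples at
100 Hz; the sample count scales with the rate).  Per frame:

* pitch p = arctan(g_y / √(g_x² + g_z²)) ∈ [−90°, 90°], and
* roll r = atan2(−g_x, g_z) ∈ (−180°, 180°]

are computed from the **frame-mean gravity vector** (averaging the vector
and then taking angles avoids wrap-around artefacts that averaging angles
would cause near ±180°); the two-argument arctangent is required for roll
to span the full circle, and the boundary values (p = ±90° when
g_x = g_z = 0; r = 180°) are returned rather than treated as errors since
noise makes them reachable.  Activity a is the **population** standard
deviation of the per-sample magnitude series ‖s(t)‖ within the frame (at
200 samples the population/sample distinction is negligible; σ is the
population convention).  Activity is rotation-invariant because the
magnitude series is.

The pitch/roll naming follows the feature equations (pitch is driven by
g_y, roll by g_x/g_z); anatomical axis descriptions are treated as
informal.  The inverse map used by the simulator is
g = (−cos p sin r, sin p, cos p cos r), the exact right inverse of the two
angle formulas (round-trip error < 1e-6°).

## Transition detection and segmentation

Each 2-s frame is merged with the five following frames into a 12-s
extended frame; consecutive extended frames overlap by 60%, realised as a
stride of round(6 × 0.4) = 2 underlying frames (4 s) — the nearest
whole-frame stride to the stated overlap.  Extended pitch/roll are
recomputed from the mean gravity over the span (exact, using the stored
per-frame mean-gravity vectors) and extended activity is the pooled
magnitude SD.

A pair of consecutive extended frames is a transition candidate when
|Δp| > θ_p or |Δr| > θ_r, with roll differences taken circularly (wrapped
to ≤180°), which matters for lateral-lie↔lateral-lie rolls near ±180°.
**θ_p = θ_r = 15°** by default; both are config-exposed.  A candidate is
confirmed only when at least `confirm_adjacent` (default 1) of its two
neighbouring pairs is also a candidate, which rejects single-pair blips
("temporary adjustment of position").  Runs of consecutive confirmed pairs
collapse to one event at the midpoint of the run's first pair.

Because an extended frame averages 12 s of gravity while the stride is
4 s, a step change of Δ degrees produces consecutive-pair differences of
at most Δ/3: orientation changes below ≈3·θ ≈ 45° are structurally
invisible to the rule, and slow drifts spread over minutes fall below
threshold entirely.  Both false-negative modes are deliberate properties
of the method, not implementation artefacts, and both are exercised in the
tests.

Segmentation walks outward from the transition point over the 2-s frames
and places each boundary at the edge of the first pair of consecutive
frames whose pitch and roll agree within tolerances (defaults θ/3 = 5°);
one stable 2-frame pair spans 4 s ≥ the 1.5-s stabilisation window, which
is why stability is assessed on frame pairs.  If the trace edge is reached
first, the boundary is clamped there and the segment flagged truncated.
Overlapping segments from nearby points are merged (interval union, first
point kept), so the output is time-ordered and disjoint.

## Posture classification

Frames are labelled by the annotated posture interval containing their
midpoint (half-open [start, end) intervals); frames whose midpoint falls in
an annotated transition are excluded — labels describe settled posture
states, and mixing ramp frames into training would blur every class.

The classifier is an RBF-kernel SVM over z-scored {p, r, a}
(standardisation parameters from the training fold only).  Hyper-parameters
are selected by stratified 3-fold grid search on macro-F1 over
C ∈ {0.1, 1, 10, 100} and γ ∈ {0.01, 0.1, 1, 10}.  Because SVM fitting is
quadratic in the number of frames and the per-frame features are heavily
redundant within a bout, the grid search runs on a stratified subsample of
1500 frames and the final fit on 4000 (proportional allocation with a
floor so scarce classes survive); prediction uses every frame.  Class
weighting is off by default and available as an option.  Everything is
deterministic given a seed.

Leave-one-pig-out (LOPO) evaluation trains on all animals but one and
tests on the held-out animal, once per animal; predictions are pooled
across folds before computing the confusion matrix (rows = true,
columns = predicted) and one-vs-rest per-class F1 = 2·TPc/(rowc + colc),
with an unweighted mean across the five classes.

## Transition kinematics

Over each segment [start, end]: duration = end − start; peak acceleration
= max ‖s(t)‖; acceleration range = the largest per-axis (max − min);
jerk = max |discrete first difference of ‖s(t)‖| × rate.  These use the
**raw** samples, so impact transients are preserved.  The pitch and roll
rates are the maximal absolute frame-to-frame angle change divided by the
frame step, computed on the **preprocessed** feature frames, so they
measure posture change speed rather than impact.  Max-type summaries were
chosen for jerk and the angle rates because the phenomenon of interest —
a hind-end stopping suddenly versus gently — lives in the extreme, not the
mean; the plain per-axis max−min reading of "range of acceleration" is
used, with the time-localised signed-swing variant left out of scope.

## Event-based evaluation

A detection coincides with an annotation when their intervals overlap
after dilating the annotation by **2 s** on each side (one frame; absorbs
video/sensor synchronisation error, whose magnitude the recording protocol
does not pin down).  Every annotation with ≥1 coinciding detection is one
TP (extra detections on the same annotation count nothing); annotations
with none are FN; detections coinciding with nothing are FP.  Precision,
recall and F1 follow; zero-denominator metrics raise a distinct signal
rather than silently returning 0, so "no detections at all" is
distinguishable from "all detections wrong".  Note that exact arithmetic on
the reference counts TP = 965, FP = 204 gives precision 0.8255, i.e. 0.825
at 3 decimals; the commonly quoted 0.826 is that value double-rounded.

## Behaviour profiles

Time budget: proportion of classified frames per posture (sums to 1).
Transition frequency: the count of transition points in each half-open
2-h window stepped by 12 min (a count per fixed-width window is a scaled
moving average; counts match the natural plot axis), full windows only,
reported at window centres.  ECDF: F(x) = #{v ≤ x}/n, right-continuous;
the pooled baseline includes the animal under comparison (a
leave-one-animal-out baseline is available behind a flag), and is exactly
the transition-count-weighted mixture of the per-animal ECDFs.

## The simulator

`synthetic_data.simulate` emulates the study conditions the pipeline is
meant for: a sow in a farrowing crate wearing a hind-end sensor for one to
four days.  Its components, with defaults:

* **Posture sequence**: semi-Markov chain over {ST, S, LL, RL, SL};
  truncated-exponential dwells (means 300/90/1200/1200/600 s, floor 45 s);
  next posture from a fixed preference matrix in which stand↔lie and
  lie↔lie moves dominate and the small-orientation-change moves
  (ST↔SL, ST↔S, S↔SL) total ≈3% of transitions — crated sows mostly
  alternate standing and lying and roll between sides, and this mix is
  also what makes ≥95% event recall attainable given the detector's
  structural ≈45° floor (ST↔SL in particular is orientation-identical and
  undetectable by design).
* **Orientations** (pitch, roll): ST (0, 0), S (−35, 0), LL (0, −90),
  RL (0, 90), SL (0, 0); standing and sternal lying differ only in
  activity, as for a real hind-end sensor on a level back.  Per-bout
  orientation jitter (SD 3–5°, clipped at 2 SD) models imperfect pose
  reproduction; sitting gets SD 15° in pitch because it is a poorly
  defined, wobbly posture — this, its scarcity and its wide activity
  spread are what make sitting the hardest class, mirroring field
  experience.
* **Transitions**: sigmoid pitch/roll ramps over 8–16 s (flat tails give
  the stabilisation plateaus segmentation needs), plus a Gaussian impact
  spike (SD 0.08 s) along the post-transition gravity direction at 80% of
  the ramp, with amplitude = the planted *abruptness* ∈ (0.2, 2.5) g₀ —
  the flopping signature and the ground truth for jerk recovery.
* **Noise**: movement jitter is Gaussian noise smoothed to ≈0.2 s
  correlation (body sway, not white noise — white jitter at 100 Hz would
  bury planted spikes in derivative artefacts), scaled per posture
  (ST 0.12 g₀ down to 0.01 g₀ for lateral lies) with per-bout log-normal
  variation; white sensor noise of 0.005 g₀ (a typical MEMS accelerometer
  floor) is added last.
* **Surge**: an optional (start_h, end_h, multiplier) window divides dwell
  means by the multiplier, emulating the nest-building transition surge
  12–18 h before farrowing.

Ground-truth posture and transition intervals tile the simulated span
exactly, and everything is reproducible from the seed.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: kneeling and other unlabelled intermediate
postures, scratching/shifting movements that caused real false positives,
multi-minute gradual posture drifts (only constructed drift cases are
tested), sensor detachment/failure, piglet contact artefacts, and real
inter-sow behavioural idiosyncrasy beyond the parameters above.  Recovery
rates on simulated data are upper bounds, not forecasts of field
performance.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: detector recovery on
ten 24-h simulations, LOPO on cohorts of six sows × 6 h (≈64 000 labelled
frames), kinematic recovery on ≈220 planted transitions, and surge
localisation on one 96-h trace simulated at 25 Hz (frame arithmetic scales
with the rate; the behavioural content is rate-independent).  Tolerances:
round-trip I/O to 6 decimals; orientation inversion to 1e-6°; activity
rotation-invariance to 1e-9; interval-tiling and budget-sum identities to
1e-9.  Ties and degenerate inputs: a step exactly on a frame edge pads
segment boundaries by half a frame so start < point < end always holds;
empty detection lists, zero-transition animals and spans shorter than one
frequency window are all defined (empty result / flagged truncated window)
rather than errors.
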