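# sowmotion

Automatic quantification of posture states and posture transitions in
farrowing sows from a single hind-end tri-axial accelerometer.

Piglet crushing is a major welfare and productivity problem in farrowing
systems, and the danger is concentrated in how the sow *changes* posture —
especially "flopping" (an abrupt standing-to-lying movement of the
hind-end) and rolling between lateral lies. `sowmotion` turns a raw
100 Hz, ±8 g₀ acceleration trace from a sensor mounted between the
tail-head and hip bones into:

1. **per-frame posture features** — the static (gravity) acceleration
   g(t) is estimated with a recursive low-pass filter
   gᵢ(t) = α·sᵢ(t) + (1−α)·gᵢ(t−1), and each 2-s frame (200 samples at
   100 Hz) is summarised by pitch p = arctan(g_y/√(g_x²+g_z²)), roll
   r = atan2(−g_x, g_z) and activity a = σ(‖s‖), the standard deviation of
   the per-sample acceleration magnitude;
2. **transition detection and segmentation** — consecutive overlapping 12-s
   extended frames flag a transition when |Δp| > θ_p ∨ |Δr| > θ_r (with
   neighbouring frame pairs required to confirm, suppressing brief
   positional adjustments), and each transition's start/end are found by
   searching outward for where the orientation re-stabilises;
3. **posture classification** — an RBF-kernel SVM over {p, r, a} assigns
   each frame one of five mutually exclusive postures: standing (ST),
   sitting (S), left lateral lie (LL), right lateral lie (RL), sternal lie
   (SL); generalisation to unseen animals is measured leave-one-pig-out;
4. **transition kinematics** — duration, peak acceleration magnitude,
   largest per-axis acceleration range, jerk (max |d‖s‖/dt|) and maximal
   pitch/roll rates, the descriptors of how controlled a lying movement was;
5. **lying-behaviour profiles** — posture time budgets, transitions per
   2-h window in 12-min steps (the pre-farrowing nest-building surge shows
   up as a spike), and per-feature ECDFs compared against a pooled
   all-animal baseline;
6. **event-based evaluation** — detections are matched to annotated
   transition intervals by overlap (annotations dilated by a 2-s sync
   tolerance); precision = TP/(TP+FP), recall = TP/(TP+FN) and their
   harmonic mean F1.

A synthetic sow-motion simulator (semi-Markov posture sequence, sigmoid
orientation ramps, planted impact spikes, band-limited movement jitter,
optional pre-farrowing transition surge) provides ground-truthed traces so
that every stage is testable without animal data.

## Worked example

```python
from sowmotion import (SimConfig, simulate, detect_and_segment, match_events,
                       metrics_from_counts, extract_features, featurize_all)

out = simulate(SimConfig(seed=42, duration_h=6.0, animal_id="sow42"))
segments = detect_and_segment(out.trace)
counts = match_events(segments, out.truth.transition_intervals, tolerance_s=2.0)
m = metrics_from_counts(counts)
print(f"detected {len(segments)} transitions: TP={counts.tp} FP={counts.fp} FN={counts.fn}")
print(f"precision={m.precision:.3f} recall={m.recall:.3f} F1={m.f1:.3f}")
```

prints

```
detected 27 transitions: TP=27 FP=0 FN=1
precision=1.000 recall=0.964 F1=0.982
```

Of the 28 posture changes planted in this 6-h simulation, 27 are detected
with no false positives; the one miss is a sternal-lie→sit change, whose
~20° orientation change falls below what the threshold rule can see through
the 12-s extended-frame averaging — the detector's documented blind spot
for small or gradual posture changes.  Featurising the
detected segments (`featurize_all(segments, out.trace,
extract_features(out.trace))`) yields the kinematic table; in this run mean
transition duration is 8.0 s, mean peak acceleration 1.96 g₀ and mean jerk
8.5 g₀/s, with the most abrupt flop reaching 3.29 g₀ and 17.6 g₀/s.

The same stages are available from the shell:

```bash
sowmotion simulate --seed 42 -o run/
sowmotion detect run/trace.csv -o run/segments.csv
sowmotion evaluate --detected run/segments.csv --annotated run/annotations.csv -o run/eval.json
sowmotion run run/trace.csv --annotations run/annotations.csv -o run/full/
```

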