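# sonimotion

Movement sonification pipelines for primate enrichment devices: turn a
chimpanzee's pushes and shakes of an instrumented object into sounds, in
real time, with every interaction logged for later analysis.

The package implements two sensing pipelines and the analyses around them:

* **Wired strain pipeline.** Four piezoelectric sensors under a Plexiglas
  panel, each read as a 10-bit integer (0–1023); the device works on the
  four-channel sum *s* ∈ [0, 4092]. A noise gate (500 counts) discards
  gentle touches during recording. The live detector discriminates
  surface-displacing *thrusts* from superficial *hits* with a two-stage
  rule: a candidate opens when *s(t)* > 1000, and a thrust event fires iff
  the sum re-read 5 ms later satisfies *s(t + 5 ms)* > 1765, after which a
  300 ms refractory period suppresses further triggers so one movement
  elicits one sound. Summed readings cross an ASCII-decimal serial line;
  malformed lines are discarded, not raised. Sensor positions induce a
  centroidal Voronoi tessellation of the panel (for four sensors, the four
  quadrant centroids).
* **Wireless acceleration pipeline.** A 3-axis accelerometer (±3 g, 8 bits
  per axis, 10 ms cadence) inside a resilient toy. The sound-driving
  parameter is **jerk**, the Euclidean norm of per-axis acceleration
  differences between consecutive samples: ‖Δa‖ = √(Δaₓ² + Δa_y² + Δa_z²).
  Jerk is invariant to any constant per-axis offset, so gravity, sensor
  bias, and steady walking cancel; shakes exceed an activation threshold
  (default 30 raw counts, adjustable per individual). A continuously-reset
  timer debounces activations: only an activation preceded by a
  refractory-length quiet period is sonified.
* **Calibration analyses.** Drop-test sessions (a 5 kg weight dropped from
  20–180 cm, five times per height) are segmented into trials by
  inter-reading gaps (new trial after ≥ 2 s; readings 0.5–2 s after their
  predecessor are rebound echoes and are discarded); each trial's feature
  is the mean of its first ≤ 10 readings, and an OLS fit of feature on
  fall height recovers the calibration line *r* = 1208.29 + 3.00·*d* + *e*
  (counts; *d* in cm). Onset-aligned, 5 ms-binned mean/CI profiles of
  repeated hit vs thrust manipulations, compared per bin with Welch's
  unequal-variance t-test, justify the stage-2 threshold: it is the lower
  95 % confidence bound of the thrust profile at the 5 ms bin.
* **Sonification and logging.** Configurable event→sound mappings (rules by
  event kind and magnitude range; constant, linear, or breakpoint gain
  curves), abstract playback sinks, and CSV session logs whose '#'-prefixed
  parameter header blocks record every threshold change mid-session.
* **Behavior coding.** Parsing of tab-delimited behavioral annotation
  exports (approach, recession, explore, tool use, poke, push, hit,
  display, proximity) and the pilot-session summary: per-individual counts,
  proximity durations, totals, and the share of session time under each
  sound condition.
* **Synthetic signals.** Seeded generators for every input above — strain
  pulses by manipulation type, full drop sessions with ground truth, and
  rest/walk/shake acceleration regimes — so the whole system runs and is
  tested without hardware.

## Worked example

```python
import sonimotion as sm

# simulate a shake session and sonify it
frames = sm.gen_accel_stream(sm.AccelRegime(mode="shake", seed=2))
events = sm.detect_shakes(frames)
print(len(events))                      # 3   (three shake bursts)

# wired pipeline: a thrust pulse passes both stages, a hit does not
thrust = sm.gen_strain_pulse(sm.PulseSpec(kind="thrust", seed=0))
print(sm.detect_thrusts(thrust))
# [DetectionEvent(t_ms=5, kind='thrust', magnitude=1905.0)]
hit = sm.gen_strain_pulse(sm.PulseSpec(kind="hit", seed=0))
print(sm.detect_thrusts(hit))           # []

# drop-test calibration: simulate, segment, fit
session = sm.gen_drop_session(seed=1)
fit, seg = sm.calibrate_session(session.readings)
print(seg.n_trials, seg.n_discarded)    # 45 66   (45 trials, echoes dropped)
print(round(fit.intercept, 1), round(fit.slope, 2), round(fit.adj_r2, 2))
# 1236.4 2.73 0.55
```

The three calibration numbers are the fitted intercept (counts at zero fall
height), the slope (extra counts per cm of fall height) and the adjusted R²
of the fit; in the noiseless limit (`residual_sd=0`) the generator's line
(intercept 1208.29, slope 3.00) is recovered to machine precision.

A CLI wraps the same functions:

```bash
sonimotion simulate drops --seed 1 --out drops.csv
sonimotion calibrate --input drops.csv --out fit.json
sonimotion simulate accel --mode shake --out shake.csv
sonimotion detect wireless --input shake.csv --out events.csv
sonimotion summarize --input src/sonimotion/data/pilot_session_synthetic.tsv --out table.csv
```

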