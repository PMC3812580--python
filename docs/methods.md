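# Methods

This note documents the models and procedures the package implements,
the parameter choices that matter, and what the synthetic generators do
and do not claim about real sensor data.

## Wired pipeline: two-stage thrust detection

The wired device reports four strain channels as 10-bit integers; all
logic operates on their sum, bounded by 4 × 1023 = 4092 counts. Three
thresholds structure the pipeline:

| parameter            | default | units  | role |
|----------------------|---------|--------|------|
| `noise_gate`         | 500     | counts | recording-mode gate: gentle touches reach ~500 counts and are ignored |
| `stage1_threshold`   | 1000    | counts | opens a detection candidate |
| `stage2_threshold`   | 1765    | counts | must still be exceeded when the sum is re-read after the delay |
| `stage2_delay_ms`    | 5       | ms     | re-read delay; also the profile bin width |
| `refractory_ms`      | 300     | ms     | suppression window after an emitted event |

All comparisons are strict (`>`). The defaults come from the drop-test
calibration of the physical panel: 1765 counts is the lower 95 %
confidence bound of the thrust profile at the 5 ms bin, which is exactly
what `profile_strain_types` recomputes from repetition data. A thrust
(surface-displacing push) stays high 5 ms after onset; a hit (superficial
strike) has already decayed, which is the entire basis of the
discrimination. The noise gate applies in calibration/recording mode
only; the live detector's stage-1 threshold subsumes it.

Design points that the prose description of the device leaves open, and
how this implementation resolves them:

* *"Re-read after 5 ms"* is implemented as the nearest frame at or after
  `t + stage2_delay_ms`; if none arrives within twice the delay the
  candidate is abandoned (real streams drop samples).
* The refractory period is measured from the stage-1 trigger time of the
  last *emitted* event; failed stage-2 candidates impose no dead time.
* The emitted event carries the second-stage sum as its magnitude and
  `t + stage2_delay_ms` as its timestamp.
* The serial transport accepts a line iff it strips to a non-empty string
  of ASCII digits. Lines with leading zeros parse to the same integer;
  signs, decimal points and non-ASCII digit characters are rejected as
  transmission noise, silently (logged at debug level).

Sensor placement: the four sensors sit at the quadrant centroids of the
panel, the centroidal Voronoi tessellation of a rectangle for n = 4.
`lloyd_step` provides the generic Lloyd iteration (grid quadrature,
nearest-generator assignment); note that for a rectangle the staggered
near-quadrant configurations decay only slowly under Lloyd iteration, so
fixed-point tests allow a few hundred iterations.

## Wireless pipeline: jerk and the continuously-reset timer

Raw acceleration is 8 bits per axis at a 10 ms cadence; the simulator
adopts the convention zero-g ≈ 128 counts and ≈ 42.5 counts/g for a ±3 g
span. Only *differences* of consecutive samples enter the jerk norm, so
this encoding is a simulator convention, not a correctness assumption:
any constant per-axis offset — gravity, bias, a linear systematic sensor
error — cancels exactly, which the translation-invariance tests assert.

The activation threshold has no canonical value (it is tuned per
individual in practice); the default of 30 raw counts is chosen so that
the synthetic rest and walk regimes stay far below it (their jerk is a
few counts) while shake bursts exceed it by a factor of several. The
debounce follows the stricter reading of the timer rule: *every*
supra-threshold activation resets the timer, whether or not it was
sonified. A sustained shake therefore produces exactly one sound — its
first activation — and nothing more until the device has been quiet for
a full refractory interval (default 300 ms, mirroring the wired
pipeline; the wireless refractory is otherwise unspecified). Streams
whose inter-sample gaps leave the 10 ± 2 ms band are rejected rather
than silently resampled.

## Drop-test calibration

Segmentation is a three-way gap rule applied to time-ordered, gated
readings: a gap ≥ 2000 ms opens a new trial; a gap ≤ 500 ms continues
the current sequence (trial or discarded echo train); a gap in between
starts a rebound sequence that is discarded. Every reading lands in
exactly one trial or the discard pile, and widening the ricochet gap can
only retain more readings — both are property-tested.

The per-trial feature is the arithmetic mean of the first
min(len, 10) readings ("up to the first 10" is read as min(len, 10)).
The calibration fit is ordinary least squares of feature on fall height
(statsmodels), reporting slope, intercept, adjusted R², the F statistic
on (1, n − 2) df, and per-coefficient t statistics.

The simulator draws each trial's feature mean as
`1208.29 + 3.00·d + N(0, σ)` and centres within-trial scatter over the
feature window, so the σ → 0 limit recovers the line to machine
precision. σ defaults to the value derived from the variance identity
R² = b²·Var(d) / (b²·Var(d) + σ²) (with the adjusted-R² correction for
one regressor) at a target adjusted R² of 0.56 under the fixed protocol
design — about 134 counts — rather than to an invented constant. With
that σ, the mean recovered slope and intercept over 100 seeded sessions
sit within ±0.15 and ±25 of the generating values; the acceptance tests
recompute this.

The hit/thrust profile analysis shifts each repetition so its first
reading is t = 0, averages within 5 ms bins, and across repetitions
forms per-bin means with Student-t 95 % confidence intervals (bins with
a single contributing repetition get a degenerate zero-width interval;
bins with fewer than two repetitions per condition get no test). The
bin-wise comparison is Welch's two-sample t-test with Satterthwaite df,
sign convention hit − thrust; the hand-written Welch statistic is
cross-checked against scipy in the tests, including the zero-variance
degenerate cases scipy warns about. On the synthetic repetition sets the
5 ms bin difference is conventionally significant (|t| > 2) with the
thrust condition higher; the exact t value depends on generator noise
and is deliberately not pinned.

## Synthetic generators: what they emulate

Strain pulses are piecewise-linear breakpoint envelopes of the
four-channel sum, split into equal channel quarters plus independent
Gaussian noise (default sd 6 counts/channel), clipped to the ADC range.
The breakpoints are configuration; the *class-defining inequalities* are
contract, validated at construction: touch peaks below the noise gate;
tap peaks between gate and stage-1; hit opens above stage-1 but can
never satisfy the two-stage rule at any onset; thrust passes both stages
and shows a secondary rise in the 70–95 ms window. Peak ordering
touch < tap < hit ≤ thrust holds by construction. Absolute magnitudes
beyond the two calibrated thresholds are not claimed to match any
physical panel.

Drop sessions emit trials at ≥ 2.1 s spacing with 12–24 samples at 10 ms
intervals; with probability 0.7 a train of 1–3 echo readings
(550–1100 counts) lands 600–900 ms after a trial's last reading, inside
the discard window by construction. Acceleration regimes are: rest
(baseline plus sd-1 noise), walk (slow sinusoid, period 600 ms,
amplitude 8 counts, plus the gravity offset), shake (80 ms
alternating-sign bursts of ±70 counts at scheduled times). These
reproduce the qualitative regime separation — rest/walk jerk of a few
counts, shake jerk of hundreds — not chimpanzee biomechanics, gait
individuality, grip damping, or piezo electromechanics. Passing tests
therefore demonstrate the correctness of the detection logic under the
stated signal structure, not field performance on real animals.

The pilot-session annotation fixture is synthetic: its per-individual
counts, proximity durations and condition schedule match the published
pilot summary exactly, but event times within the session are
constructed (deterministically), since the raw annotation timeline was
never published.

Problem sizes used by the acceptance script — one 45-trial session, a
50-pulse train, a 200-pulse stress mix, 100-seed recovery in the test
suite — are the study's own protocol sizes or modest multiples chosen to
make the measured quantities stable across seeds.

## Known limitations

* The package analyses streams; it does not talk to hardware. Serial and
  Bluetooth transports exist only as the line-parsing contract and the
  frame containers; playback sinks are null/file/pluggable objects.
* Quantities that depend on the original unpublished raw recordings (the
  exact regression statistics of the physical panel, its discarded-reading
  count, the exact hit/thrust t value) are covered by parameter-recovery
  and qualitative checks, not numeric reproduction.
* Segmentation assumes input readings are already noise-gated and
  time-ordered; it does not re-gate.
* The Lloyd solver uses grid quadrature, adequate for sensor placement
  (sub-mm) but not a high-precision CVT solver.
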