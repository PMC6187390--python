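# Methods

## Signal model and the Activity Index

A wrist accelerometer measures gravity plus body-movement acceleration in
device coordinates.  The pipeline works entirely on the vector magnitude
`A = sqrt(ax² + ay² + az²)`, which is invariant under any fixed rotation of
the device, so wear orientation never enters the analysis.  Over a short
epoch the gravity contribution to `A` is approximately constant and equals
the epoch mean μ; the population standard deviation σ of the magnitudes
about μ therefore measures net movement acceleration.  σ² is proportional
to the mean squared net acceleration and hence to the kinetic energy of
wrist movement; σ (rather than σ²) is used because typical per-epoch
values are well below 1 g and the square would compress the scale.  The
Activity Index of a reporting interval is the sum of its epoch σ's.

This gravity treatment is an approximation: a posture change *within* an
epoch moves μ and leaks a gravity component into σ.  With 5-s epochs the
leakage is small (an epoch rarely spans more than one posture change) and
it is the price of needing no high-pass filter, which keeps the method
implementable on-device.  No axis calibration (offset/gain) is applied.

### Parameters

| parameter | default | meaning |
|---|---|---|
| sample rate | 20 Hz | device configuration; all constants below derive from it |
| epoch length | 5 s | σ window; N = rate × epoch = 100 samples |
| reporting interval | 60 s | AI window; M = interval / epoch = 12 epochs |
| day anchor | 12:00 | analysis days run noon-to-noon so a night's sleep is never split |

Epochs are non-overlapping and clock-aligned (the first epoch starts at a
whole multiple of the epoch length past the minute), so M epochs tile
each minute exactly; a recording-aligned mode exists
(`epoch_sigma(..., clock_aligned=False)`).  Partial epochs and partial
minutes at the recording edges are dropped, not padded — a σ estimated
from a short tail would be biased.  The population (1/N) form of the
standard deviation is used, exactly as the defining formula reads, not
the 1/(N−1) sample estimator; at N = 100 the difference is 0.5%, but the
choice is fidelity, not statistics.

## Activity levels

Minute AIs map to five ordered levels through cut points 0.1 / 0.5 / 2.0
/ 4.0, derived from a 14-activity wear test (the per-activity max / min /
mean AI table ships as `REFERENCE_ACTIVITIES`).  Intervals are half-open
and lower-inclusive — `[0, 0.1)` rest/sleep, …, `[4.0, ∞)` vigorous — so
the partition is total; the verbal description of the cuts is ambiguous
exactly at the boundaries, and assigning boundary values upward is the
convention adopted here.  Note the reference table's ranges overlap the
cuts (stair descent without arm swing peaks at AI 8.1 while its mean is
moderate); classification is strictly per-minute by AI value, so
occasional minutes of an activity can score above its nominal level.

## Sleep detection

Phase I scans the minute-AI sequence once, left to right, committing each
minute.  The initial state is awake iff the first AI ≥ 0.1, the upper
bound of resting-level AI.  Thereafter a minute's state follows from the
previous minute's state, a threshold T, and a look-ahead vote over the
*following* minutes (the current minute is excluded; windows truncate at
the series end):

* awake → asleep: current AI < T and ≥ `sleep_minth` of the next
  `window1_min` AIs are < T;
* asleep → awake: current AI > T and < `wakeup_minth` of the next
  `window2_min` AIs are < T.

AI exactly equal to T keeps the previous state (the criteria are strict
inequalities).  T is the strict threshold (0.1) except during the *fuzzy
period* — the `fuzzy_min` minutes after an awakening that interrupted a
sleep episode — where the relaxed threshold (0.2) applies, in both
branches.  This models the elevated probability of falling back asleep
shortly after a nocturnal awakening and gives the detector hysteresis: a
borderline-still trace (AI between 0.1 and 0.2) is scored as sleep right
after such an awakening but as wakefulness during the day.  Applying the
relaxed threshold to the wake judgment as well is deliberate: with a
strict-only wake test, a subject who fell back asleep under the relaxed
criterion would be re-woken one minute later by the same borderline AI,
producing a sleep/wake oscillation.

Phase II extracts maximal sleep runs and merges consecutive runs whose
separating awake gap is shorter than `merge_gap_min` (30 min), repeating
left to right to a fixed point (a single pass suffices: merging two runs
never changes the gaps to their neighbours).  "Gap shorter than the
bound" — rather than "fragment shorter than the bound" — is the reading
that eliminates fragmented sleep: people experience a night with brief
awakenings as one sleep period.  A merged period's duration and quality
(mean minute AI over the span) include the absorbed gaps, so restless
nights correctly score longer-but-worse.

Only the 0.1 bootstrap value is prescribed by the level analysis; the
remaining constants (windows 10 min, votes 8 and 3, fuzzy 15 min, merge
gap 30 min) are configuration with defaults chosen so that planted sleep
in synthetic days is recovered within the look-ahead window length.  All
are exposed in `SleepDetectionConfig`.

## Regularity Index

Hourly AI vectors (24 sums of 60 minute-AIs, noon first) summarize a
day's routine; using hours rather than 1440 minutes deliberately discards
minute-level noise so the RI reflects the coarse daily pattern.  RI is
the Pearson product-moment correlation between two days' vectors —
day *i* vs *i*−1 (day-to-day) or *i* vs *i*−7 (week-to-week).  Pearson is
validated by the bundled example week: its six published day-to-day RI
values are reproduced to four decimals (a rank correlation would not
match them).  References are calendar-based, so a missing day leaves the
dependent RIs missing rather than silently comparing non-adjacent days.
A zero-variance day (flat hourly pattern) has no defined correlation and
yields NaN, never 0 — 0 would assert "uncorrelated", which the data
cannot support.  Days with incomplete minute coverage are rejected unless
explicitly allowed, because a partially observed hourly pattern biases
the correlation unpredictably.

## Daily summary

Per noon-to-noon day: total AI `t_ai` (= sum of the 1440 minute AIs =
sum of the hourly vector, conserved to 1e-9); day-to-day RI `d_ri`; sleep
hours `sl_t` (all detected periods, naps included — the parameter means
time asleep or at rest, not night sleep only); sleep quality `sl_q`
(duration-weighted mean minute AI over all sleep periods); hours per
activity level `t_level` (aggregation "at level L or above" is left to
the caller as Σ t_L + t_{L+1} + …); and post-wake capability
`a[x]_t_[level]`, the hours spent at ≥ a given level within x hours of
waking.  The post-wake window anchors at the offset of the *main*
(longest; ties → later onset) sleep period, since the parameter is meant
to capture capability after adequate rest; anchoring at every wake event
is possible via `post_wake_activity` directly.  The default query is
(3 h, moderate), the clinically motivated example of exercise capacity
after a night's rest.

## Synthetic data generator

`simulate_recording` emits, per schedule segment, a 1 g gravity vector at
a random fixed orientation (optionally drifting as a slow random walk)
plus isotropic zero-mean Gaussian noise on the three axes, optionally
quantized to the 3.9 mg step of a ±8 g 12-bit sensor.  Isotropic
Gaussian noise is the simplest model with controllable magnitude
second-moment structure — which is all the pipeline consumes.  The
per-axis scale is *calibrated*: for axis noise s around unit gravity the
magnitude is a scaled noncentral-chi variable whose standard deviation
falls below s as s grows (≈ 0.88 s at s = 0.5), so the exact moment
relation — E[A²] = 1 + 3s² and E[A] by Gauss–Hermite × Gauss–Laguerre
quadrature over the parallel and perpendicular noise components — is
inverted with a root finder.  Hour-averaged recovered epoch σ matches the
target to well under 2% (the residual is N = 100 sampling error, not
calibration bias).

`simulate_minute_ai` bypasses the raw stage: each minute's AI is
M·σ times a mean-one lognormal factor (log-sd `jitter`, default 0.1),
strictly positive and exactly the target at zero jitter.  Preset
schedules cover a regular week (8 h night sleep, contrasting daytime
blocks), a fragmented night (10- and 15-min awakenings inside
23:00–06:30 sleep), a two-day shift-disruption scenario, and a day
embedding all 14 reference activities at their reference mean AIs.

What the generator does *not* emulate — and therefore what passing tests
do not establish about real data: biomechanical wrist kinematics
(periodic gait accelerations, hand gestures), posture changes within an
epoch, non-wear intervals, device axis miscalibration, and temperature
or light channels.  Tests against it validate the pipeline's arithmetic,
invariances and decision logic under the stated signal model, not
field accuracy of sleep scoring.

## Numerical and degenerate-input choices

* Raw CSV timestamps are naive local clock time (the noon-to-noon
  convention is clock-based); DST is not modelled.  Written with ms
  precision and 12 significant digits, so write→read round trips are
  exact to < 1e-9 g.
* The measured sample rate is the median inter-sample interval; a > 1%
  disagreement with a declared rate warns and keeps the measured value;
  > 10% jitter or duplicate timestamps are errors, not repairs.
* Gaps from device swaps are flagged (incomplete day windows), never
  imputed; downstream stages require complete days unless overridden.
* Sleep detection refuses series shorter than its look-ahead window;
  empty day lists and empty sleep-period lists return empty/None rather
  than raising.
* Problem sizes in the test suite: full-day raw simulations (1.73 M
  samples) appear in a handful of end-to-end checks; most raw-signal
  tests use minutes-long recordings, and the 50-day sleep-recovery study
  runs at minute resolution.
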