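# actimetry

Analytics for 24/7 wrist-worn accelerometry.  `actimetry` turns raw
tri-axial acceleration from a wrist device (±8 g MEMS sensor, 20 Hz) into
clinically interpretable daily parameters: a minute-wise **Activity Index
(AI)**, a five-level physical-activity classification, automatic
**sleep-duration detection**, a **Regularity Index (RI)** quantifying how
repeatable a subject's daily routine is, and per-day monitoring summaries.
It is aimed at digital-health and actigraphy researchers who need
device-orientation-independent activity quantification from free-living
recordings, without activity-type recognition or vendor software.

## The model

For samples *a*ₓ, *a*ᵧ, *a*_z (in g) the orientation-free signal magnitude
is

&nbsp;&nbsp;&nbsp;&nbsp;*A*ⱼ = √(*a*ₓⱼ² + *a*ᵧⱼ² + *a*_zⱼ²).

Within each 5-s epoch (N = 100 samples at 20 Hz) the population standard
deviation

&nbsp;&nbsp;&nbsp;&nbsp;σ = √( (1/N) Σⱼ (*A*ⱼ − μ)² ),&nbsp;&nbsp; μ = (1/N) Σⱼ *A*ⱼ

measures net body-movement acceleration: the epoch mean μ absorbs the
quasi-static 1 g gravity component, so a motionless wrist gives σ = 0 at
any orientation.  The Activity Index over a reporting interval is the sum
of its M epoch σ's (M = 12 for one-minute AI):

&nbsp;&nbsp;&nbsp;&nbsp;AI = Σₖ σₖ ,  k = 1…M.

Minute AIs map to five activity levels by fixed cut points
(rest/sleep < 0.1 ≤ sedentary < 0.5 ≤ light < 2.0 ≤ moderate < 4.0 ≤
vigorous).  Sleep is detected on the minute-AI sequence by a two-phase
state machine (threshold + look-ahead vote, then merging of briefly
interrupted sleep runs), and the Regularity Index of day *i* is the
Pearson correlation between the 24-element hourly AI vectors of day *i*
and day *i*−1 (or day *i*−7 for the week-to-week RI).  Analysis days run
noon-to-noon so a night's sleep lies inside one day.

## Worked example

The package bundles one week of hourly AI values from a free-living
recording (`actimetry.datasets`).  Computing the RI trend:

```python
from actimetry import load_example_week, ri_trend
print(ri_trend(load_example_week()).to_frame().to_string(index=False))
```

```
       day   ri_day  ri_week
2018-05-09      NaN      NaN
2018-05-10 0.707786      NaN
2018-05-11 0.838567      NaN
2018-05-12 0.648427      NaN
2018-05-13 0.142985      NaN
2018-05-14 0.110455      NaN
2018-05-15 0.439546      NaN
```

Each `ri_day` value correlates that day's hourly activity pattern with
the previous day's: 10–12 May show a fairly regular routine (RI 0.65–0.84),
13–14 May a disrupted one (RI ≈ 0.11–0.14).  `ri_week` is empty because
no day has a reference one week earlier within the span.

The full chain runs from a raw CSV (here a synthetic recording with a
fragmented night sleep — 23:00–06:30 with 10- and 15-min awakenings):

```sh
actimetry simulate --preset fragmented_sleep --seed 7 -o raw.csv
actimetry run raw.csv -o out/
cat out/summary.json
```

```json
[
    {
        "day": "2018-05-09",
        "t_ai": 1334.906199549392,
        "d_ri": null,
        "sl_t": 7.5,
        "sl_q": 0.11169593455479852,
        "t_0": 7.083333333333333,
        "t_1": 0.0,
        "t_2": 15.916666666666666,
        "t_3": 1.0,
        "t_4": 0.0,
        "a3_t_3": 1.0
    }
]
```

`t_ai` is the day's total AI; `sl_t = 7.5` h is the merged sleep duration
(the two brief awakenings are folded into the main period, which is why
the sleep quality `sl_q` ≈ 0.11 is worse than a still night's ≈ 0.05);
`t_0`…`t_4` are hours per activity level; `a3_t_3 = 1.0` says the subject
managed one hour at moderate-or-higher intensity within three hours of
waking.  Intermediates (`minute_ai.csv`, `levels.csv`, `sleep_states.csv`,
`hourly_ai.csv`, `ri.csv`) are written alongside, and each pipeline stage
is also available as its own subcommand (`ai`, `levels`, `sleep`, `ri`,
`summary`) or library function.

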