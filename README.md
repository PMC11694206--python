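# sprintwindow

Tools for analysing **how footballers reach and leave their match peak
speed**, from raw 10 Hz wearable-GNSS speed traces.

Standard sprint testing starts players from a standstill, but match peak
speeds are reached from *flying starts*: a player already moving at
~5–10 km/h accelerates over roughly four seconds to a 29–32 km/h peak, then
decelerates faster than they accelerated — without coming to a stop.
`sprintwindow` quantifies exactly this peri-peak dynamic for sports
scientists and club performance staff working with athlete-tracking data:

1. **Peak validation.** Raw GNSS speed feeds contain implausible spikes, so
   the fastest raw sample cannot be trusted.  Samples above a physiological
   cap (44.45 km/h) are marked missing; the *match peak speed* is then the
   fastest candidate v\* that (a) exceeds the sprint threshold
   (> 25.2 km/h) and (b) is **corroborated**: some other effort in the same
   match reached ≥ v\* − 1 km/h (e.g. a 32.7 km/h peak requires a second
   effort at ≥ 31.7 km/h).  Uncorroborated maxima are demoted to the
   next-fastest sprint-bout maximum.
2. **Peri-peak windowing.** The 20-second window around each validated peak
   (10 s before to 10 s after, 201 samples at 0.1 s) is extracted on the
   trace's own grid and reduced to speeds at the 21 integer-second offsets.
3. **Estimation statistics.** Speed changes between consecutive one-second
   intervals are summarized as paired mean differences with 95% t-intervals
   and Cohen's *d* (standardized by the average condition SD,
   s_av = √((SD₁² + SD₂²)/2)); positions are compared with independent mean
   differences.  |d| is banded at 0.2 / 0.6 / 1.2 / 2.0 / 4.0 into
   trivial … extremely large, or *unclear* when the CI spans zero.
4. **Synthetic cohorts.** Because real club GNSS data are proprietary, a
   seeded simulator generates ground-truthed 90-minute traces —
   semi-Markov intermittent locomotion, mono-exponential sprints with a
   faster deceleration constant, AR(1) observation noise, spike artifacts
   and timing gaps — so every stage is testable end to end.

## Worked example

```python
from sprintwindow import (FilterConfig, filter_speeds, find_match_peak,
                          extract_window, per_second_profile, run_pipeline,
                          simulate_cohort, study_roster)
from sprintwindow.synthetic_data import SimConfig

cohort = simulate_cohort(SimConfig(), study_roster(), seed=7)  # 90 traces
trace, truth = cohort[0]

cfg = FilterConfig()
filtered = filter_speeds(trace, cfg)          # spikes removed: 1
peak = find_match_peak(filtered.trace, cfg)
# match peak: 29.99 km/h at t=2049.6 s
#   (corroborated by 29.49 km/h at t=4855.6 s)

profile = per_second_profile(extract_window(filtered.trace, peak))
[round(profile.value(k), 2) for k in range(-5, 6)]
# [10.64, 17.92, 24.31, 26.79, 28.42, 29.99, 17.69, 10.62, 8.25, 7.37, 7.4]

report = run_pipeline(t for t, _ in cohort)   # 90 windows retained
{d.pair: d for d in report.interval_diffs}["4-3"]
# interval 4-3: +5.85 km/h (95% CI 5.64, 6.06), d=3.00 -> very large
```

Reading the numbers: this player's valid peak was 29.99 km/h, reached from
~10.6 km/h five seconds earlier (a flying start) and already back down to
~7.4 km/h ten seconds later — the per-second profile drops faster after the
peak than it rose before it.  Across the 90 simulated windows the largest
pre-peak acceleration lands in the 4→3 s interval, the largest deceleration
immediately after the peak.

The same workflow is available from a shell:

```bash
sprintwindow simulate --out data/ --seed 7
sprintwindow analyze --traces data/ --metadata data/metadata.csv --out report/
sprintwindow tables --report report/
```

## Reference summary statistics

`sprintwindow.reference` transcribes published per-position summary tables
from an elite cohort (20 outfield players, six matches, 90 observations:
per-second mean ± SD speeds, peak speeds, interval effect sizes).  They
calibrate the simulator's defaults and give the aggregation arithmetic
published numbers to reconcile against — e.g. n-weighted pooling of the
per-position means reproduces the published pre-peak interval differences
(+4.25 km/h at 4→3 s), and the peak-row means reproduce the published
between-position differences (FB − CM = −1.38 km/h read column-minus-row).

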