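# Methods

This note documents the models, conventions and numerical choices behind
`sprintwindow`, and what the synthetic-data tests do and do not establish
about real athlete-tracking data.

## Data model and grid contract

The unit of input is one player-match **speed trace**: integer milliseconds
from session start and speed in km/h, nominally on a 100 ms (10 Hz) grid.
Halves or split sessions are separate trace files; no wall-clock alignment
is attempted, because the analysis is relative to the peak, not to match
time.  Inter-sample intervals within 100 ± 10 ms are treated as device
jitter; anything larger is a *gap*.  Gaps and filtered samples are carried
as explicit missing values end to end — the I/O and filtering layers never
interpolate, since an interpolated value could fabricate or displace a
peak.  Rows out of time order are an integrity error rather than being
sorted, on the grounds that unordered exports indicate an upstream fault
that should be surfaced, not papered over.

## Peak validation

Filtering and validation operate on raw (device-untreated) speeds:

* samples above **44.45 km/h** are physiologically implausible for running
  and are marked missing;
* a candidate peak must exceed the **25.2 km/h sprint threshold**;
* a candidate v\* must be **corroborated** by another effort within
  **1 km/h** of it.  "Another effort" is operationalized as a sample
  ≥ v\* − 1 lying outside the candidate's own contiguous run above that
  level, i.e. the speed must fall below v\* − 1 somewhere between the two
  samples.  This is the weakest reading that excludes samples belonging to
  the same sprint while imposing no arbitrary time separation.  The
  corroborating sample is *not* required to exceed the sprint threshold
  itself; the published worked example (32.7 valid iff some effort reached
  ≥ 31.7) constrains only the margin.  When several samples qualify, the
  fastest (earliest on ties) is recorded as the witness.

If the global maximum fails corroboration it is demoted and the
next-highest sprint-bout maximum is tested with the margin recomputed, so
one spurious sub-cap spike cannot void a whole player-match.  Candidate
order is descending speed, ties broken by earlier occurrence.  The witness
comparison carries a 10⁻⁹ km/h slack so that decimal speeds sitting exactly
on the margin boundary are not lost to binary float representation.

Validity under this rule is *not* monotone in the margin: widening the
margin lowers the witness level (which can create witnesses) but also
widens the candidate's own run (which can swallow them).  The rule is
therefore verified against a brute-force enumeration oracle on random
traces rather than through a monotonicity property.

Sprints are additionally typed *explosive* vs *leading* by whether any of
the 5 samples in the 0.5 s before the first super-threshold sample lies in
the high-speed-running band (19.8–25.2 km/h).

## Windowing and per-second reduction

The peri-peak window spans −10 s to +10 s at 0.1 s, 201 slots, slot 0 being
the peak sample.  Slots align to the trace's own grid anchored at the peak
(nearest sample within ±10 ms); there is no resampling.  Windows truncated
by the trace boundary are retained with missing slots, and every
per-interval statistic uses the n actually available at that interval —
discarding truncated windows would bias against late-match peaks.

The default per-second value is the **instantaneous** sample at each
integer-second offset, reading the published design ("speeds registered at
one-second intervals") literally; a **block-mean** alternative (mean of the
10 slots of each second, sign-symmetric about the peak, averaging the
non-missing slots) is provided because per-second tables of this kind are
sometimes computed that way.  The two agree exactly on constant windows.

## Estimation statistics

Paired comparisons (consecutive one-second intervals within windows) use
the exact paired t-interval for the mean difference.  Cohen's *d*
standardizes by the average condition SD, s_av = √((SD(a)² + SD(b)²)/2) —
the estimation-statistics convention for repeated measures — not by the SD
of the differences: the published interval effects (e.g. a 4.25 km/h
difference reported as d = 0.68 against condition SDs ≈ 6.3 km/h) are only
consistent with the condition-SD standardizer.  The CI of d uses the
repeated-measures normal approximation Var(d) ≈ (1/n + d²/2n)·2(1 − r),
with r the Pearson correlation of the paired columns; a noncentral-t
construction was considered and rejected as needless precision, since d
feeds a banding six coarse categories wide.  The exact standardizer and
d-CI method behind the published values are not stated there, so
reconstruction of printed d values is approximate by nature and is not
asserted anywhere; the printed (d, CI) pairs are instead used to validate
the *classifier*.

Independent comparisons (between-position peak speeds) default to the
classical pooled-variance two-sample t-interval — matching the common
two-independent-groups default of estimation-statistics software — with
Welch available; d standardizes by the pooled SD with the standard
large-sample variance approximation.  Degenerate zero-variance inputs give
width-zero mean CIs and a ±∞ d (classified by |d|).

Magnitude bands on |d|: < 0.2 trivial, then small, moderate, large, very
large, extremely large at 0.6 / 1.2 / 2.0 / 4.0, each cut-point belonging
to the larger band.  A CI spanning zero — including endpoints exactly at
zero, the conservative reading of "crossed" — overrides the band with
*unclear*.  No multiple-testing adjustment is applied across the 18
consecutive intervals, mirroring the published analysis.

Position-level tables pool with n-weights (Σnᵢmᵢ/Σnᵢ).  For intervals where
every window has both offsets, the interval table's mean difference equals
the difference of pooled position means exactly (asserted in tests).  Note
that the published tables reconcile this way only pre-peak; the post-peak
rows there do not (plausibly truncated late-match windows), so
reconciliation checks are restricted to pre-peak intervals, and the
pre-peak check is asserted to 0.01 km/h — one unit in the last printed
digit, the propagation floor for arithmetic on 2-dp-rounded inputs.

## Synthetic match generator

The generator emulates the study conditions: ~90-minute traces (54,000
samples), five playing positions with peak-speed targets at the published
per-position means ± SDs, flying starts ~9 ± 2 km/h, and deceleration
faster than acceleration with no return to standstill.

* **Baseline**: semi-Markov locomotor states (stand 0.3, walk 4.5, jog 9.0,
  run 14.5 km/h) with geometric dwell times (means 3–6 s) and fixed
  transition propensities, smoothed with a 1.5 s moving average.  Only the
  marginal speed distribution matters downstream, so dwell structure is
  deliberately simple.
* **Sprints**: 5 events per trace, placed in the interiors of equal match
  segments so windows never cross trace boundaries.  Speed rises from the
  flying-start value to the target peak over 5 s as a mono-exponential with
  τ_acc = 1.5 s, normalized so the peak sample attains the target exactly,
  then decays toward a 7 km/h floor with the faster τ_dec = 0.9 s
  (τ_dec < τ_acc is enforced as a config invariant).  One event carries the
  match peak; a second is placed 0.2–0.7 km/h below it so the 1 km/h
  corroboration rule holds by construction even under observation noise;
  the rest stay ≥ 1.2 km/h below.  Overlays blend into the baseline with
  1 s linear cross-fades.
* **Observation layer**: AR(1) Gaussian noise (ρ = 0.85, marginal SD
  0.25 km/h) — Doppler-derived GNSS speed noise is autocorrelated, not
  white.  The injected peak samples themselves are emitted noise-free so
  the ground-truth maximum is attained exactly and parameter-recovery tests
  have a well-defined target; all other samples carry noise.  Spike
  artifacts (Poisson, mean 2/trace, uniform 45–60 km/h) and optional gap
  deletions are injected away from sprint neighbourhoods and trace edges,
  with their locations recorded as ground truth.

Determinism is bitwise under a fixed seed; cohort generation derives
per-trace seeds as SHA-256(master seed, player, match) mod 2³¹, so a cohort
regenerates identically and is stable under roster edits.  The built-in
study roster reproduces the published cohort shape — 20 players (4 CD,
3 FB, 5 CM, 5 WM, 3 FW) over 6 matches with absences spread evenly to give
per-position counts (20, 10, 19, 24, 17), 90 observations in total.

**What the simulator does not emulate**: tactical context, opponent
pressure, genuinely irregular sprint shapes (stutter steps, curved runs),
per-device noise differences, within-player match-to-match repeatability,
or variable deceleration timing — post-peak between-window variability is
consequently smaller than in real data near +1…+4 s.  Passing
parameter-recovery and bookkeeping tests therefore establishes that the
pipeline is correct under controlled conditions, not that real club data
would yield these particular profiles.

## Problem sizes and numerical conventions

The test suite and the acceptance script run full-scale where the science
requires it: the simulated acceptance cohort is the complete 90-observation
roster at 90-minute duration; the peak-rule oracle comparison uses 1,000
random traces; Monte-Carlo CI coverage uses 1,000 replicates at n = 90
pairs (asserted within 95 ± 2 points).  Smaller 10-minute traces are used
only for per-trace unit tests where duration is irrelevant.

Other conventions: sample SD uses ddof = 1 (defined as 0 for n = 1 in
summary tables); CSV speeds are written with `repr` precision and read with
round-trip float parsing, so write→read is bit-identical and reruns on
identical inputs produce byte-identical reports; display rounding (2
decimals) happens only in the CLI `tables` command, never in stored
outputs.
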