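# Methods

## The measurement model

A subject walks 5 m in front of a motorized platform while performing
metronome-paced 2 Hz head yaw.  Five sensors record the trial at their own
clocks: three IMUs (head, chest, pelvis yaw, 125 Hz), a marker-tracking
camera (horizontal pixel offset of an abdominal LED, 40 Hz) and an
ultrasonic ranger (subject–platform distance, 20 Hz).  All analysis starts
by linearly interpolating every stream onto one uniform grid restricted to
the streams' common overlap.  The analysis rate defaults to 100 Hz: above
the Nyquist content of the 40/20 Hz streams, below the IMU rate, and cheap.
Linear interpolation was chosen over splines or sample-and-hold because it
is exact on affine signals (a testable property) and introduces no
overshoot.

Lateral position is reconstructed with a small-angle pinhole model,
`lateral_cm = pixel_offset · distance_cm / focal_px` (focal length a config
input, default 1000 px).  The walk's "ideal" path is the virtual straight
line from the first to the last sample of the lateral trace; subtracting it
absorbs constant offsets and linear drift and pins both endpoints of the
deviation series to zero.  The forward coordinate is deliberately not
reconstructed: every trajectory metric depends only on perpendicular
offsets as a function of time, so deviation-vs-time with the first-to-last
chord is sufficient and needs no platform odometry.

## Metrics

* **XCoB** `= 100 · mean|xᵢ| / (height/2)` — mean unsigned deviation in %
  of half body height.
* **RP / LP** — means of the positive local-maximum values and of the
  magnitudes of negative local-minimum values; a side with no qualifying
  extremum contributes 0 rather than NaN.
* **MLW** — upper envelope interpolated linearly through the local maxima
  (endpoints included), lower envelope through the minima; MLW is the
  largest upper-minus-lower gap at any sample.  A plain max−min range mode
  is available as a config fallback; the two coincide for stationary
  oscillations.
* **MRT** `= max|yaw|` per segment over the trial.
* **CP ratio** `= mean |Cᵢ + Pᵢ|` with `Cᵢ = chestᵢ / max|chest|`,
  `Pᵢ = pelvisᵢ / max|pelvis|` (signs preserved, per-trial normalization;
  trial averaging happens downstream).  It lies in [0, 2], is invariant to
  separately rescaling either segment, and decreases monotonically with the
  chest–pelvis phase offset for equal-frequency sinusoids:
  `(4/π)|cos(φ/2)|`, i.e. 4/π ≈ 1.273 in phase, 2√2/π ≈ 0.900 at 90°, 0 in
  anti-phase.
* **MoH** — successive alternating head-yaw extrema define half-cycle
  excursions `|y_{k} − y_{k−1}|`; excursions departing a rightward
  (positive) extreme pool as "right rotation", those departing a leftward
  extreme as "left rotation"; each pool reports mean and population SD.  A
  perfectly metronome-paced sinusoid yields SD = 0, so the SD measures
  movement variability.

**Extremum detection** is shared by all metrics: the signal is smoothed
with a 0.25 s moving average, peaks are located on the smoothed copy
(plateaus resolve to their center), and each index is then refined to the
raw signal's extreme within half a smoothing window.  The refinement step
matters: the moving average attenuates a 2 Hz sinusoid by ~36 %, so peak
*values* are always read from the raw series.

**Yaw baseline.**  Yaw is unwrapped across ±180° jumps before resampling,
then a baseline is subtracted so left/right are signed around zero.  The
default baseline is the median of the whole series, which is a robust zero
for periodic locomotor yaw even when the recording starts mid-oscillation;
an initial-window median (`baseline_window_s`) is available for protocols
that guarantee quiet stance at the start.  With an initial-window baseline
a trial that begins mid-swing acquires a spurious offset that breaks the
anti-phase CP-ratio null, which is why the series median is the default.

## The acuity engine

The chart has 11 tumbling-E sizes from logMAR 1.0 (20/200) to 0.0 (20/20)
in 0.1 steps; a letter's detail subtends 10^logMAR arcmin so its height is
5·10^logMAR arcmin.  A session presents 5 random orientations (0/90/180/
270°) per size for 75 ms each, descending size by size.  SVA starts at the
chart top; dynamic sessions start 4 sizes above the subject's smallest
correct SVA size (clamped to the chart top).  Termination: all five
optotypes of a size missed, chart exhausted (all 55 answered), or — in
locomotion modes — the walk ends ("walk_complete"), with the partial level
scored as presented.  Locomotion sessions accept a list of walk passes and
accumulate presentations across them; standing sessions recycle their head
trace, since a standing subject simply keeps turning.

Dynamic presentations are velocity-gated: head yaw velocity (central
difference after 20 ms smoothing) must exceed +120 deg/s for right modes or
fall below −120 deg/s for left modes.  Successive presentations are at
least 1 s apart (the subject answers between letters), which yields the
realistic 3–6 answered letters per 5 m pass.

Scoring is letter-by-letter: each correct optotype is worth 0.02 logMAR
(5 per 0.1 line), every letter on sizes larger than the start size is
credited, and the threshold is `1.1 − 0.02 · total correct` — so a perfect
55/55 run scores 0.0 and a session with nothing correct from the top
scores 1.1.  The DVA result is the dynamic-minus-static threshold
difference; the abnormality flag raises for a decrement strictly greater
than the configured limit, default 0.2 logMAR (0.3 is the conservative
alternative, selectable in config).

## The synthetic generator

The generator emulates the study conditions — a 5 m walk at 1 m/s (5 s),
2 Hz head yaw — with the minimal kinematic structure that admits analytic
ground truths: sinusoidal sway `A_s sin(2πf_s t) + d·t`, sinusoidal
head/chest/pelvis yaw, Gaussian sensor noise, and native 125/40/20 Hz
sampling (optionally with ±1 ms timestamp jitter) so the resampling path is
always exercised.  Defaults: sway 5 cm at 1 Hz (stride-locked
medial-lateral sway at half the ~2 Hz step rate; 1 Hz also makes the
default 5 s walk hold whole cycles, which the closed forms assume), head
amplitude 40° (half-cycle excursions of 80°, in the range reported for
instructed 2 Hz head turning), chest/pelvis 7°/6° with 180° phase offset
(healthy reciprocal pattern; 0° is the rigid "en bloc" pattern), sensor
noise 0.2 cm / 0.5°, camera focal 1000 px at a 150 cm platform distance.
Trunk rotation reuses the sway frequency, being likewise stride-locked.

Ground truths are the whole-cycle closed forms: `mean|A sin| = 2A/π` for
XCoB, MLW = 2A, MRT = amplitude, CP ratio `(4/π)|cos(φ/2)|`, MoH excursion
2·head amplitude.  Observers follow a 4-AFC psychometric rule: above their
effective threshold (static threshold + dynamic penalty while the head
moves) they answer correctly except for lapses (default 2 %); below it they
guess at chance (default 25 %).  Letter scoring therefore carries a small
optimistic bias below threshold (lucky guesses add credit before an
all-missed line terminates); with 200 seeded sessions the median recovered
threshold stays within 0.1 logMAR of truth at every chart level (worst
observed ≈ 0.08 at the chart top, where the most sub-threshold lines
remain to guess through).

The platform controller interprets the distance-keeping rule as a
multiplicative ±10 % motor-signal adjustment evaluated per 20 Hz control
tick whenever the gap leaves [target, target + 10 cm], with a warning flag
on any sample below the 150 cm target.  A multiplicative rule cannot start
a stopped platform, so the platform launches at the subject's own pace
(estimated from the first second of positions) and a small minimum-speed
kick covers acceleration from standstill.  A 10 %-mismatched launch
converges back above the target within a second and the gap then stays
within ±20 cm.

What the generator does **not** emulate: step-by-step gait events
(heel-strikes, double support), stride-linked harmonics, non-stationary
sway, head pitch/roll, realistic motor dynamics, or any coupling between
postural sway and acuity.  Passing tests therefore demonstrate that the
*analysis* is correct on signals with known structure, not that real
patients will produce these numbers; cohort tests check only the
qualitative direction of the healthy-vs-patient contrasts, never the
clinical magnitudes.

## Statistics

Groups are compared with the Mann–Whitney U test exactly as the report
tables present it: U is the smaller one-sided statistic, Z uses the
tie-corrected variance with a 0.5 continuity correction (so Z ≤ 0, the
sign convention of common statistics packages), and the two-sided p is
exact for n₁·n₂ ≤ 400 — computed from the permutation distribution of the
rank sum via a subset-sum dynamic program over doubled midranks, with
`p = 2·min(P(U ≤ u), P(U ≥ u))` capped at 1 — and the normal approximation
otherwise.  Alpha is 0.05 and no multiple-testing correction is applied.
Group summaries report mean, sample SD, median and the 25th/75th
percentiles with linear interpolation.

## Numerical choices and edge cases

* Resampling grid: `t0 = max` of stream starts, `n = ⌊(t1−t0)·rate+ε⌋+1`
  samples, so an exact-length overlap keeps its final sample.
* Deviation endpoints are exactly zero by construction of the chord
  subtraction.
* A side with no peaks (RP/LP, MoH) reports 0, not NaN; a head trace with
  fewer than two extrema raises "no head turns detected"; a segment with
  zero maximal rotation raises "degenerate normalization" rather than
  dividing by zero.
* Acuity thresholds and decrements are rounded at 1e-10 so floating-point
  dust never flips the strictly-greater abnormality comparison.
* All randomness (generator, observers, orientation sequences) flows from
  explicit integer seeds; identical seeds give bit-identical streams and
  presentation logs.

## Problem sizes

Default simulations are 5 s trials (625 IMU samples); the cohort analyses
use 15 + 7 subjects with two trials each; staircase recovery uses 200
seeded sessions per chart level.  The full test suite and the
reproduction script each complete in seconds on one CPU.
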