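# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `headturnkit`, in the spirit of the methods
documentation of mature scientific packages.

## Signal model and conventions

A recording is a uniformly sampled (nominally 100 Hz) stream of tri-axial
acceleration (g, ±8 g range) and angular velocity (deg/s, ±2000 deg/s
range) from one of three sites: head, thoracic, lumbar. The internal
segment frame is **(AP, ML, V-up)**: x anterior–posterior, y mediolateral,
z vertical pointing up. A resting accelerometer reads (0, 0, −1) g in this
frame; yaw is rotation about V (gyro channel 2), pitch about ML
(channel 1). Mounting misalignment is modelled as a proper rotation C with
`v_sensor = C @ v_segment` (intrinsic Z-Y-X Euler angles in the scenario
config); alignment estimates R ≈ Cᵀ.

Sign conventions are fixed by the package, since rectified processing makes
them unobservable downstream: the yaw axis is oriented within 90° of the
nominal sensor vertical, pitch within 90° of nominal ML. This assumes the
sensor is mounted roughly right-side-up (rotations under ~45°), which holds
for taped head/trunk sensors.

## Turn detection

The two-filter scheme: (1) smooth yaw with a zero-phase FIR whose impulse
response is an Epanechnikov kernel, k(u) ∝ (1−u²)₊, spanning 1.476 s;
(2) rectify; (3) candidate turns are local maxima above 15 °/s;
(4) boundaries come from the rectified output of a lighter 0.383 s
Epanechnikov FIR — the last crossing below 5 °/s before the peak and the
first after; (5) the *unfiltered* aligned yaw between the boundaries is
integrated (trapezoid) to the amplitude, its sign giving direction and its
absolute maximum the peak velocity; (6) candidates with overlapping
boundary intervals are unioned (one physical turn can put several maxima on
the heavily smoothed trace); (7) same-direction candidates under 10° within
1/3 s of a neighbour are iteratively merged, re-integrating over the union,
stopping at a 10 s merged duration; (8) turns under 10° are discarded;
(9) turns are classed small (< 45°) or large (≥ 45°; the boundary closes on
the large side).

Numerical decisions:

* Kernel support is rounded to an odd tap count (147 taps at 100 Hz for
  1.476 s; 37 for 0.383 s) so the filter is exactly symmetric, hence
  zero-phase. Edges are handled by reflection, which preserves DC.
* Amplitude and peak velocity are measured on the unfiltered signal
  (config-switchable): smoothing attenuates peaks and would bias amplitudes
  low. Boundary truncation at the 5 °/s crossings still loses the pulse
  tails, so amplitude errors are small and systematically negative — on
  synthetic free-living scenarios the median signed error is ≈ −0.1%.
* Boundary searches are capped at 5 s either side of a peak; a signal that
  never drops below threshold within the cap is truncated there.
* Direction comes from the sign of the integral, not the sign at the peak,
  which is robust for jerky multi-peak turns.

An intrinsic consequence of the main filter: a unit-sum Epanechnikov kernel
of duration T has maximum value 1.5/T ≈ 1.016 s⁻¹, so the smoothed peak of
*any* isolated pulse of integral A is at most ≈ 1.016·A per second. With
the 15 °/s peak threshold, isolated smooth turns below ≈ 14.8° can never
trigger detection regardless of their speed; the 10° amplitude discard is
binding mainly for fragments produced inside jerky turns and for merged
candidates. The test suite therefore checks the 10° rule at the
consolidation stage (candidate level) and the end-to-end floor with 8°
(rejected) and 16° (detected) pulses.

## Sensor-to-segment alignment

**Prescribed movements.** Shake/nod/jump sequences are detected as three
rectified yaw-gyro peaks > 40 °/s, then three pitch peaks > 40 °/s, then
three acceleration-magnitude peaks > 10 m/s² (1 m/s² prominence floor to
reject ripple around the 1 g baseline), successive peaks < 2 s apart, in
shake→nod→jump order within a 30 s scan window. For each movement the
rotation axis is estimated from per-axis RMS over the window: the
highest-RMS axis is dominant, and the full 3-vector direction takes each
component's magnitude from its RMS and its sign from its covariance with
the dominant axis — exact for rotation about a fixed axis, robust at
1 °/s noise (median recovery error ≈ 0.3°). The pitch axis ρ̂ (nod) and yaw
axis ŷ (shake) are generally not exactly orthogonal, so the frame is
re-orthogonalised: r̂ = ρ̂ × ŷ (normalised), then ŷ ← r̂ × ρ̂, and
R = [r̂; ρ̂; ŷ] stacked as rows is a proper rotation. Shake/nod axes with
|ρ̂·ŷ| > 0.9 are rejected as degenerate.

**Walking bouts.** Over a bout of ≥ 100 steps, cyclic AP/ML accelerations
average out and the mean accelerometer vector points along gravity. With
the unit mean vector (a_AP, a_ML, a_V), the tilt angles are
θₐ = arcsin(a_AP) and θₘ = arcsin(a_ML), and the tilt rotation is composed
as R = R_ML(θₐ)·R_AP(−θₘ) — exact for single-axis tilts; for combined
tilts the residual against the minimal (Rodrigues) rotation that maps the
mean vector onto the vertical stays below the 0.01 g vertical-residual
budget for tilts within ±20° (both constructions are available;
`method="exact"` selects the Rodrigues route). A mean-acceleration
magnitude outside [0.8, 1.2] g rejects the bout as non-quasi-static. The
transform carries a gravity-cancellation offset of +1 g on the vertical
axis so aligned vertical acceleration averages ≈ 0 over the bout; under
the opposite resting-read convention (rest = +1 g up) the same offset is
written −1 g. Walking alignment resolves tilt only (2 DoF): gravity cannot
observe heading, so yaw mounting offsets remain — harmless for turn
metrics, which use the vertical-axis rate.

**Timeline.** Prescribed events and long bouts merge into a timeline in
which each sample uses the most recent source. A long bout starting within
10 minutes after a prescribed event is treated as the same reattachment
interval and the prescribed transform wins (it resolves all 3 DoF). Spans
before the first source are flagged unaligned and excluded from turn
detection.

## Activity and wear

**Steps.** The lumbar vertical channel is de-meaned, integrated
(cumulative sum) and differentiated with a Gaussian-derivative filter —
the fixed-scale analogue of a Gaussian continuous-wavelet smoothing. The
default scale σ = 0.05 s passes impact content around the typical 2 Hz
step frequency while suppressing sample noise; initial contacts are minima
of the smoothed signal with prominence ≥ 0.1 g, collapsed when closer than
0.25 s. De-meaning makes detection exactly invariant to constant bias.
Steps with inter-step gaps ≤ 2.5 s share a bout (the bout boundary is a
package choice); bouts under 5 steps are shuffling and contribute no
steps; bouts of ≥ 100 steps qualify for gravity alignment.

**Counts and wear.** A raw sum of tri-axial acceleration always contains
gravity and would never reach zero, so the per-epoch count is defined as
the sum over samples of | ‖a‖ − 1 g | with a 0.02 g per-sample deadband —
a static or unworn sensor genuinely produces zero counts. One-second
epochs aggregate to counts per minute. Non-wear is a run of zero-count
minutes totalling ≥ 90, tolerating interruptions of ≤ 2 consecutive
nonzero minutes; bursts interrupt the run without resetting it and do not
count toward the 90 (runs start and end on zero minutes). Worn and
non-worn intervals partition the day exactly, so wear + non-wear = 24 h on
complete days.

## Summaries and reliability

A day is valid at ≥ 10 h wear. Cohort CVs are computed from each subject's
pooled per-turn values across the week and then averaged across subjects —
pooled per-turn variability, not variability of daily means.

ICC(2,k) is the average-measures intraclass correlation from the two-way
ANOVA decomposition. The default is the consistency form
(MS_rows − MS_error)/MS_rows; the absolute-agreement form
(MS_rows − MS_error)/(MS_rows + (MS_cols − MS_error)/n) is available by
flag, since the usual citation of "ICC(2,k)" does not pin the qualifier
down. Degenerate matrices with no between-subject variance return 1.0 with
a warning. Under the generating model x_ij = μ + b_i + e_ij the consistency
form estimates k·σ²ᵦ/(k·σ²ᵦ + σ²ₑ), which the tests recover within ±0.01 at
500 subjects; the implementation agrees with an independent brute-force
ANOVA oracle to < 1e−10.

Subset reliability restricts to subjects with ≥ 5 valid days (first five
chronological), pairs each subject's k-day subset mean with their 5-day
mean, computes the two-column ICC for every one of the C(5,k) subsets, and
averages — per-subset values are exposed alongside the mean. k = 5 gives
ICC 1 by construction. Bands: < 0.50 poor, [0.50, 0.75) moderate,
[0.75, 0.90) good, ≥ 0.90 excellent (boundaries closed on the upper band).

## Synthetic scenarios: what they emulate, and what not

The generator scripts everything downstream stages must detect: turn
pulses (Hann-shaped; jerky turns as ≥ 2 overlapping sub-pulses at 40%
overlap; integral equals the scripted amplitude to < 0.1%), head–trunk
coupling (a head-site script mirrors `coupling × pulse` on the lumbar yaw,
so coupling 1 is en-bloc motion and coupling 0 a pure volitional
head-on-body turn; a lumbar-site script with coupling 0 turns the trunk
under a space-stable head — a stabilizing turn), calibration sequences
built to the detection thresholds, gait as zero-mean impact waveforms of
0.5 g depth at the scripted cadence, mounting rotations, i.i.d. Gaussian
noise (defaults 1 °/s gyro, 0.01 g accel — plausible MEMS figures, chosen
once), and non-wear gaps with zero angular rate and a frozen gravity
vector whose residual noise sits below the activity-count deadband.

Default scripted kinematics follow the free-living ranges reported for
healthy adults: amplitudes 20–90°, peak velocities 1.5–2.5 × amplitude per
second, inter-turn gaps ≥ 2 s. Evaluation scenarios use 20 seeds × 20
turns (detector metrics), 100 mixed volitional/stabilizing events
(classification), 5 cadences × 10 seeds × 100 steps (gait) and a 24 h day
with a scripted 7.6 h gap (wear) — sizes chosen to make Monte-Carlo
variation small relative to the acceptance margins.

What passing these tests does *not* show: the Hann pulse is a stand-in for
real velocity profiles, whose empirical distribution is unknown; there is
no soft-tissue artifact, no biomechanical gait–turn coupling (turning
while walking), no curved-walking confound, and the step impact waveform
is idealised (the step detector's scale cliff is sharper on this waveform
than on real gait). Results on real recordings depend on behaviours the
generator does not produce.

## Known limitations

* Heading is unresolved under walking-only alignment; head-on-body
  differencing assumes both sensors share the vertical axis after
  alignment, not a common heading.
* Integer-sample synchronisation only (no sub-sample interpolation): at
  100 Hz the residual ≤ 5 ms is negligible against 1.476 s smoothing.
* The small-turn floor (≈ 14.8° for isolated smooth turns) is intrinsic to
  the 1.476 s main filter with a 15 °/s threshold, not a configuration
  artifact.
* Counts-based wear detection keys on the lumbar (or any single) sensor;
  which sensor governed wear in multi-sensor deployments is a user choice,
  and per-sensor wear can disagree.
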