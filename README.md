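# headturnkit

Continuous monitoring of head turns from body-worn inertial sensors.

People reorient their head thousands of times a day — scanning before
crossing a street, tracking a conversation partner, stabilizing gaze while
the trunk turns. Quantifying this behaviour in daily life matters for
vestibular rehabilitation, concussion recovery and fall-risk research, but
it requires turning a week of raw head/trunk IMU data into interpretable
kinematics. `headturnkit` implements that full pipeline:

* **Ingestion** (`imu_io`) — CSV recordings (tri-axial accelerometer in g,
  gyroscope in deg/s, nominally 100 Hz) from head, thoracic and lumbar
  sites; duplicate-sample removal and resampling onto a uniform grid,
  cross-correlation synchronisation on shared tap events, clock-drift
  correction, and segmentation into local calendar days.
* **Sensor-to-segment alignment** (`alignment`) — arbitrary sensor mounting
  is rotated into anatomical axes either from prescribed calibration
  movements (3 head shakes > 40 °/s, 3 nods > 40 °/s, 3 jumps > 10 m/s²,
  successive peaks < 2 s apart; per-axis RMS picks the yaw/pitch axes, the
  cross product completes the frame) or, when no calibration was performed,
  from long walking bouts (≥ 100 steps), where the mean accelerometer
  vector points along gravity and the tilt angles
  θₐ = arcsin(ā_AP), θₘ = arcsin(ā_ML) define a tilt-only rotation.
* **Turn detection** (`turndetect`) — the vertical-axis angular velocity is
  smoothed by a zero-phase FIR with an Epanechnikov-kernel impulse response
  of 1.476 s; rectified local maxima above 15 °/s mark turns; a lighter
  0.383 s filter locates the start/end as crossings below 5 °/s; the raw
  signal between the boundaries is integrated to the turn amplitude.
  Same-direction sub-10° fragments within 1/3 s merge (up to 10 s), then
  turns under 10° are discarded, and survivors are classed small (< 45°)
  or large.
* **Head-on-body turns** (`hob`) — the detector runs on the head-minus-
  lumbar yaw difference; each turn is **volitional** when the head's
  in-space peak velocity exceeds the trunk's, **stabilizing** otherwise.
* **Activity & wear** (`activity`) — steps from the lumbar vertical
  acceleration via integration and Gaussian-wavelet differentiation
  (initial contact = minima of the smoothed signal; bouts of < 5 steps are
  shuffling); wear time from per-minute activity counts, with ≥ 90
  consecutive zero-count minutes (tolerating ≤ 2-minute bursts) marked
  non-wear.
* **Summaries & reliability** (`summaries`) — per-day aggregates (a valid
  day has ≥ 10 h wear), coefficients of variation, and ICC(2,k) reliability
  of k-day subsets against the 5-day average, with the standard
  poor/moderate/good/excellent bands at 0.50 / 0.75 / 0.90.
* **Synthetic scenarios** (`synthgen`) — a first-class generator of
  multi-hour three-sensor recordings with scripted turns (including jerky
  multi-peak and en-bloc vs head-on-body coupling), calibration sequences,
  gait, mounting misalignment, noise and non-wear gaps, plus the exact
  ground truth — so every stage is testable end to end without human data.

## Worked example

```python
import headturnkit as htk
from headturnkit import hob

cfg = htk.ScenarioConfig(
    duration_h=0.05,
    turn_scripts={
        "head": [
            htk.TurnScript(onset_time=20, amplitude=60, peak_velocity=120, segment_coupling=0.0),
            htk.TurnScript(onset_time=50, amplitude=-35, peak_velocity=70, segment_coupling=1.0),
            htk.TurnScript(onset_time=80, amplitude=90, peak_velocity=150, n_subpeaks=3, segment_coupling=0.0),
        ],
        "lumbar": [htk.TurnScript(onset_time=110, amplitude=75, peak_velocity=110, segment_coupling=0.0)],
    },
    gyro_noise_sd=1.0,
    seed=42,
)
recs, truth = htk.simulate_recording(cfg)
for r in recs.values():
    r.frame = "segment"  # identity mounting in this example

turns = htk.detect_turns(recs["head"].gyro[:, 2], fs=100)
classified = hob.detect_hob_turns(recs["head"], recs["lumbar"])
```

Formatting the detected events prints:

```
head turn  20.01- 20.99 s  dir +1  amplitude  60.0 deg  peak  122.0 deg/s  [large]
head turn  50.04- 50.96 s  dir -1  amplitude  35.0 deg  peak   70.4 deg/s  [small]
head turn  79.93- 80.96 s  dir +1  amplitude  89.9 deg  peak  151.3 deg/s  [large]
head-on-body  20.01 s  amplitude  59.8 deg  -> volitional (head 122 vs lumbar 3 deg/s)
head-on-body  79.92 s  amplitude  89.9 deg  -> volitional (head 151 vs lumbar 2 deg/s)
head-on-body 110.05 s  amplitude  74.8 deg  -> stabilizing (head 2 vs lumbar 112 deg/s)
independent fraction: 1.00
```

All four scripted turns are recovered within a fraction of a degree (the
jerky three-peak 90° turn is consolidated into one event); the en-bloc
−35° turn produces no head-on-body event, the trunk rotation under a
stable head is labelled stabilizing, and the reported peak velocities
include the scripted 1 °/s sensor noise.

A command-line interface mirrors the library
(`headturnkit simulate | sync | align | detect | detect-hob | activity |
reliability`); see `headturnkit --help`.

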