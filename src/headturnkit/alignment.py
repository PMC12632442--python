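"""Sensor-to-segment alignment.

Two routes map arbitrary sensor mounting axes onto anatomical head/trunk
axes:

* **Prescribed movements** — the wearer shakes the head three times (yaw),
  nods three times (pitch) and jumps three times (vertical acceleration)
  after every sensor reattachment. The gyroscope direction with the highest
  per-axis RMS during each movement gives the provisional yaw and pitch
  axes; their cross product completes a right-handed rotation.
* **Long walking bouts** (>= 100 steps) — cyclic AP/ML accelerations cancel
  over many strides, so the mean accelerometer vector points along gravity.
  Two tilt angles, theta_a = arcsin(mean_AP) and theta_m = arcsin(mean_ML)
  (components of the unit mean vector), build a tilt-only rotation; heading
  is deliberately left unresolved (gravity cannot observe it).

Internal segment frame is (AP, ML, V-up); a resting accelerometer reads
-1 g on V. The walking route additionally cancels gravity so the aligned
vertical acceleration averages ~0 over the bout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ._rotations import is_proper_rotation, rot_x, rot_y, rotation_between
from .imu_io import ImuRecording

GRAVITY_MS2 = 9.80665

#: detection thresholds for the prescribed shake/nod/jump sequence
SHAKE_NOD_PEAK_DPS = 40.0
JUMP_PEAK_MS2 = 10.0
MAX_PEAK_SPACING_S = 2.0
SEARCH_WINDOW_S = 30.0


class AlignmentError(ValueError):
    """Raised when an alignment cannot be constructed from the given data."""


@dataclass
class PrescribedEvent:
    """One detected shake -> nod -> jump calibration sequence."""

    shake_peaks: tuple[float, float, float]
    nod_peaks: tuple[float, float, float]
    jump_peaks: tuple[float, float, float]
    window: tuple[float, float]


@dataclass
class RotationTransform:
    """Proper rotation mapping sensor-frame vectors into the segment frame
    (``v_segment = R @ v_sensor``), with an optional gravity-cancellation
    offset (walking provenance only) added to the rotated accelerometer."""

    R: np.ndarray
    gravity_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )  # g, added to rotated accel
    provenance: str = "prescribed"  # prescribed | walking
    valid_from: float = 0.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.gravity_offset = np.asarray(self.gravity_offset, dtype=float)
        if not is_proper_rotation(self.R, atol=1e-9):
            raise AlignmentError("R is not a proper rotation (orthonormal, det +1)")
        if self.provenance not in ("prescribed", "walking"):
            raise AlignmentError(f"unknown provenance {self.provenance!r}")


def _peak_triplets(
    times: np.ndarray, max_spacing: float
) -> list[tuple[float, float, float]]:
    """Non-overlapping runs of 3 successive peaks each < max_spacing apart."""
    out = []
    i = 0
    while i + 2 < times.size:
        if (
            times[i + 1] - times[i] < max_spacing
            and times[i + 2] - times[i + 1] < max_spacing
        ):
            out.append((float(times[i]), float(times[i + 1]), float(times[i + 2])))
            i += 3
        else:
            i += 1
    return out


def detect_prescribed_movements(rec: ImuRecording) -> list[PrescribedEvent]:
    """Find shake/nod/jump sequences in a sensor-frame recording.

    Shake = 3 rectified yaw-gyro peaks > 40 deg/s; nod = 3 rectified
    pitch-gyro peaks > 40 deg/s; jump = 3 acceleration-magnitude peaks
    > 10 m/s^2; successive peaks < 2 s apart; shake -> nod -> jump ordering
    within a 30 s scan window. Returns an empty list when absent.
    """
    if rec.frame != "sensor":
        raise ValueError("prescribed-movement detection expects a sensor-frame recording")
    fs = rec.fs
    t = rec.time_s
    min_dist = max(1, int(round(0.3 * fs)))
    yaw_idx, _ = find_peaks(
        np.abs(rec.gyro[:, 2]), height=SHAKE_NOD_PEAK_DPS, distance=min_dist
    )
    pitch_idx, _ = find_peaks(
        np.abs(rec.gyro[:, 1]), height=SHAKE_NOD_PEAK_DPS, distance=min_dist
    )
    amag = np.linalg.norm(rec.accel, axis=1) * GRAVITY_MS2
    jump_idx, _ = find_peaks(
        amag, height=JUMP_PEAK_MS2, prominence=1.0, distance=min_dist
    )
    shakes = _peak_triplets(t[yaw_idx], MAX_PEAK_SPACING_S)
    nods = _peak_triplets(t[pitch_idx], MAX_PEAK_SPACING_S)
    jumps = _peak_triplets(t[jump_idx], MAX_PEAK_SPACING_S)

    events: list[PrescribedEvent] = []
    ni = ji = 0
    for sh in shakes:
        while ni < len(nods) and nods[ni][0] <= sh[2]:
            ni += 1
        if ni >= len(nods) or nods[ni][0] - sh[0] > SEARCH_WINDOW_S:
            continue
        nd = nods[ni]
        while ji < len(jumps) and jumps[ji][0] <= nd[2]:
            ji += 1
        if ji >= len(jumps) or jumps[ji][0] - sh[0] > SEARCH_WINDOW_S:
            continue
        jp = jumps[ji]
        events.append(
            PrescribedEvent(
                shake_peaks=sh,
                nod_peaks=nd,
                jump_peaks=jp,
                window=(sh[0] - 0.5, jp[2] + 0.5),
            )
        )
        ni += 1
        ji += 1
    return events


def _dominant_direction(gyro: np.ndarray) -> np.ndarray:
    """Unit 3-vector of the rotation axis during a single-axis movement.

    Per-axis RMS picks the dominant sensor axis; the other components get
    their magnitude from their RMS and their sign from the covariance with
    the dominant axis (exact for noise-free rotation about a fixed axis).
    """
    rms = np.sqrt(np.mean(gyro**2, axis=0))
    dom = int(np.argmax(rms))
    signs = np.sign(np.sum(gyro * gyro[:, dom : dom + 1], axis=0))
    signs[dom] = 1.0
    v = rms * signs
    return v / np.linalg.norm(v)


def alignment_from_prescribed(
    rec: ImuRecording, event: PrescribedEvent
) -> RotationTransform:
    """Rotation from one prescribed-movement event.

    The pitch axis (rho) comes from the nod window, the yaw axis (y) from
    the shake window; roll = rho x y, then y is recomputed as roll x rho so
    the stacked rows (roll=AP, rho=ML, y=V) form a proper rotation. Signs
    are oriented against the nominal mounting (yaw axis within 90 degrees of
    sensor +Z, pitch within 90 degrees of sensor +Y).
    """
    t = rec.time_s

    def window(peaks: tuple[float, float, float]) -> np.ndarray:
        m = (t >= peaks[0] - 0.5) & (t <= peaks[2] + 0.5)
        return rec.gyro[m]

    rho = _dominant_direction(window(event.nod_peaks))  # pitch / ML
    yhat = _dominant_direction(window(event.shake_peaks))  # yaw / V
    if yhat[2] < 0:
        yhat = -yhat
    if rho[1] < 0:
        rho = -rho
    if abs(np.dot(rho, yhat)) > 0.9:
        raise AlignmentError(
            "shake and nod axes are nearly parallel; alignment rejected"
        )
    roll = np.cross(rho, yhat)
    roll /= np.linalg.norm(roll)
    yhat = np.cross(roll, rho)
    yhat /= np.linalg.norm(yhat)
    R = np.vstack([roll, rho, yhat])
    return RotationTransform(R=R, provenance="prescribed", valid_from=event.window[1])


def walking_tilt_rotation(mean_accel: np.ndarray, method: str = "matrix") -> np.ndarray:
    """Tilt-only rotation mapping the unit mean accelerometer vector towards
    (0, 0, -1).

    ``method="matrix"`` uses the two-angle construction
    R = R_ML(theta_a) @ R_AP(-theta_m) with theta_a = arcsin(a_AP),
    theta_m = arcsin(a_ML) — exact for single-axis tilts. ``method="exact"``
    is the minimal rotation taking the mean vector onto the vertical
    (independent cross-check for composed tilts).
    """
    a = np.asarray(mean_accel, dtype=float)
    a = a / np.linalg.norm(a)
    if method == "exact":
        return rotation_between(a, np.array([0.0, 0.0, -1.0]))
    theta_a = np.rad2deg(np.arcsin(np.clip(a[0], -1, 1)))
    theta_m = np.rad2deg(np.arcsin(np.clip(a[1], -1, 1)))
    return rot_y(theta_a) @ rot_x(-theta_m)


def alignment_from_walking(
    rec: ImuRecording,
    bout,
    min_steps: int = 100,
    method: str = "matrix",
) -> RotationTransform:
    """Tilt alignment from a long walking bout (gravity reference).

    ``bout`` is an :class:`~headturnkit.activity.WalkingBout` (anything with
    ``start``, ``end`` and ``n_steps``). The mean accelerometer vector over
    the bout must be quasi-static (magnitude within [0.8, 1.2] g). The
    returned transform carries a gravity-cancellation offset so that the
    aligned vertical acceleration averages ~0 over the bout.
    """
    if bout.n_steps < min_steps:
        raise AlignmentError(
            f"walking bout has {bout.n_steps} steps; need >= {min_steps}"
        )
    m = (rec.time_s >= bout.start) & (rec.time_s <= bout.end)
    if not np.any(m):
        raise AlignmentError("walking bout lies outside the recording")
    abar = rec.accel[m].mean(axis=0)
    mag = float(np.linalg.norm(abar))
    if not 0.8 <= mag <= 1.2:
        raise AlignmentError(
            f"mean acceleration magnitude {mag:.2f} g outside [0.8, 1.2] g; "
            "bout is not quasi-static"
        )
    R = walking_tilt_rotation(abar, method=method)
    return RotationTransform(
        R=R,
        gravity_offset=np.array([0.0, 0.0, 1.0]),  # cancels the -1 g rest read
        provenance="walking",
        valid_from=float(bout.start),
    )


def apply_transform(rec: ImuRecording, tf: RotationTransform) -> ImuRecording:
    """Rotate a sensor-frame recording into the segment frame.

    Gyro and accel are both rotated; the gravity offset (walking provenance)
    is added to the rotated accelerometer only.
    """
    if rec.frame != "sensor":
        raise ValueError("apply_transform expects a sensor-frame recording")
    out = rec.copy()
    out.gyro = rec.gyro @ tf.R.T
    out.accel = rec.accel @ tf.R.T + tf.gravity_offset
    out.frame = "segment"
    return out


@dataclass
class AlignedInterval:
    """One validity interval of the alignment timeline."""

    start: float
    end: float
    transform: RotationTransform | None  # None = unaligned (excluded downstream)


def build_alignment_timeline(
    rec: ImuRecording,
    prescribed_events: list[PrescribedEvent],
    walking_bouts: list,
    min_steps: int = 100,
    same_interval_window_s: float = 600.0,
) -> list[AlignedInterval]:
    """Merge prescribed-movement and long-walking-bout alignment sources
    into a timeline of validity intervals covering the recording.

    Each sample is covered by the most recent applicable transform. A
    walking transform starting within ``same_interval_window_s`` of a
    prescribed event is assumed to belong to the same reattachment interval
    and is dropped (prescribed preferred). The stretch before the first
    source is flagged unaligned (``transform=None``).
    """
    sources: list[RotationTransform] = []
    for ev in sorted(prescribed_events, key=lambda e: e.window[0]):
        sources.append(alignment_from_prescribed(rec, ev))
    prescribed_times = [tf.valid_from for tf in sources]
    for bout in sorted(walking_bouts, key=lambda b: b.start):
        if bout.n_steps < min_steps:
            continue
        if any(
            0 <= bout.start - pt < same_interval_window_s for pt in prescribed_times
        ):
            continue
        sources.append(alignment_from_walking(rec, bout, min_steps=min_steps))
    sources.sort(key=lambda tf: tf.valid_from)

    t0, t1 = float(rec.time_s[0]), float(rec.time_s[-1])
    timeline: list[AlignedInterval] = []
    if not sources:
        return [AlignedInterval(t0, t1, None)]
    if sources[0].valid_from > t0:
        timeline.append(AlignedInterval(t0, sources[0].valid_from, None))
    for i, tf in enumerate(sources):
        end = sources[i + 1].valid_from if i + 1 < len(sources) else t1
        timeline.append(AlignedInterval(tf.valid_from, end, tf))
    return timeline


def transforms_to_records(timeline: list[AlignedInterval]) -> list[dict]:
    """JSON-serialisable view of an alignment timeline."""
    out = []
    for iv in timeline:
        rec: dict = {"start": iv.start, "end": iv.end}
        if iv.transform is None:
            rec["aligned"] = False
        else:
            rec["aligned"] = True
            rec["R_row_major"] = iv.transform.R.ravel().tolist()
            rec["gravity_offset"] = iv.transform.gravity_offset.tolist()
            rec["provenance"] = iv.transform.provenance
        out.append(rec)
    return out
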