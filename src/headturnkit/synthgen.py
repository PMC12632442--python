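"""Synthetic three-sensor IMU scenario generator with scripted ground truth.

Emulates the phenomenology of free-living head/trunk recordings well enough
to exercise every downstream stage: discrete yaw turn pulses (optionally
jerky, multi-peaked), en-bloc vs head-on-body coupling between the head and
lumbar segments, prescribed shake/nod/jump calibration sequences, periodic
gait impacts, static gravity with configurable sensor mounting misalignment,
additive Gaussian sensor noise, and zero-motion non-wear gaps.

Velocity pulses are Hann (raised-cosine) shaped: smooth, compactly
supported, with the analytic identity ``integral = peak x duration / 2``.
Jerky turns are sums of ``n_subpeaks`` overlapping Hann sub-pulses (40%
overlap), which preserves the scripted amplitude exactly while producing
distinct local maxima. Real free-living velocity profiles are more varied;
the pulse is a stand-in, not an empirical claim.

Conventions: segment frame is (AP, ML, V-up); a resting accelerometer reads
(0, 0, -1) g; yaw is the gyroscope's V (index 2) channel, pitch the ML
(index 1) channel. A mounting rotation C (intrinsic Z-Y-X Euler, degrees)
maps segment vectors into sensor vectors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._rotations import euler_zyx
from .imu_io import ImuRecording, SITES

GRAVITY_MS2 = 9.80665
#: accel noise sd used inside non-wear gaps; far below the activity-count
#: per-sample deadband so that "zero counts" is achievable by construction.
NONWEAR_ACCEL_NOISE_SD = 2e-4


@dataclass
class TurnScript:
    """One scripted discrete yaw turn.

    ``amplitude`` is signed (sign = direction) in degrees; ``peak_velocity``
    is the magnitude in deg/s. ``segment_coupling`` is the fraction of the
    motion mirrored on the *other* segment: for a head-site script, the
    lumbar yaw receives ``coupling x pulse`` (1 = en-bloc, 0 = pure
    head-on-body); for a lumbar-site script, the head receives
    ``coupling x pulse`` (0 = head held still in space while the trunk
    turns, i.e. a stabilizing head-on-body turn).
    """

    onset_time: float  # s
    amplitude: float  # deg, signed
    peak_velocity: float  # deg/s, magnitude
    n_subpeaks: int = 1
    segment_coupling: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude == 0:
            raise ValueError("amplitude must be nonzero")
        if self.peak_velocity <= 0:
            raise ValueError("peak_velocity must be positive")
        if self.n_subpeaks < 1:
            raise ValueError("n_subpeaks must be >= 1")
        if not 0.0 <= self.segment_coupling <= 1.0:
            raise ValueError("segment_coupling must lie in [0, 1]")


@dataclass
class GaitBout:
    """A scripted walking bout placed on the lumbar vertical channel."""

    start: float  # s
    n_steps: int
    cadence: float = 2.0  # steps/s
    impact_g: float = 0.5  # impact dip depth in g


@dataclass
class ScenarioConfig:
    """Full description of a synthetic recording; the seed fully determines
    the output."""

    duration_h: float = 1.0
    fs: float = 100.0
    turn_scripts: dict[str, list[TurnScript]] = field(default_factory=dict)
    gait_bouts: list[GaitBout] = field(default_factory=list)
    prescribed_movement_times: list[float] = field(default_factory=list)
    nonwear_intervals: list[tuple[float, float]] = field(default_factory=list)
    mounting_rotation: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )  # intrinsic Z-Y-X Euler, degrees, per site
    gyro_noise_sd: float = 1.0  # deg/s
    accel_noise_sd: float = 0.01  # g
    seed: int = 0
    start_epoch: float = 1704067200.0  # 2024-01-01 00:00:00 UTC

    @property
    def duration_s(self) -> float:
        return self.duration_h * 3600.0

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioConfig":
        d = json.loads(Path(path).read_text())
        d["turn_scripts"] = {
            site: [TurnScript(**ts) for ts in lst]
            for site, lst in d.get("turn_scripts", {}).items()
        }
        d["gait_bouts"] = [GaitBout(**g) for g in d.get("gait_bouts", [])]
        d["nonwear_intervals"] = [tuple(iv) for iv in d.get("nonwear_intervals", [])]
        d["mounting_rotation"] = {
            k: tuple(v) for k, v in d.get("mounting_rotation", {}).items()
        }
        return cls(**d)


@dataclass
class TrueTurn:
    """Ground-truth record of one scripted turn on one source signal."""

    site: str  # head | thoracic | lumbar | head_on_body
    start: float
    end: float
    amplitude: float  # deg, signed
    direction: int
    klass: str | None = None  # volitional | stabilizing (head_on_body only)


@dataclass
class GroundTruth:
    """Everything the scenario scripted, for downstream evaluation."""

    true_turns: list[TrueTurn] = field(default_factory=list)
    true_steps: list[float] = field(default_factory=list)
    true_nonwear: list[tuple[float, float]] = field(default_factory=list)
    true_mounting: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def turns_for(self, site: str, min_amplitude: float = 0.0) -> list[TrueTurn]:
        return [
            t
            for t in self.true_turns
            if t.site == site and abs(t.amplitude) >= min_amplitude
        ]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def make_turn_profile(
    amplitude: float, peak_velocity: float, n_subpeaks: int = 1, fs: float = 100.0
) -> np.ndarray:
    """Sampled yaw angular-velocity pulse whose time-integral equals
    ``amplitude`` and (for a single peak) whose maximum equals
    ``peak_velocity``.

    Sub-pulses each carry ``|amplitude|/n_subpeaks`` and overlap by 40% of
    their duration, yielding ``n_subpeaks`` distinct local maxima.
    """
    if amplitude == 0:
        raise ValueError("amplitude must be nonzero")
    if peak_velocity <= 0 or fs <= 0:
        raise ValueError("peak_velocity and fs must be positive")
    t_sub = 2.0 * abs(amplitude) / (n_subpeaks * peak_velocity)
    n_sub = int(round(t_sub * fs))
    if n_sub < 2:
        raise ValueError(
            f"infeasible pulse: amplitude {amplitude} deg at {peak_velocity} deg/s "
            f"with {n_subpeaks} sub-peak(s) implies a {t_sub * 1e3:.1f} ms sub-pulse, "
            f"under 2 samples at {fs} Hz"
        )
    spacing = 0.6 * t_sub  # 40% overlap between consecutive sub-pulses
    total = t_sub + (n_subpeaks - 1) * spacing
    n = int(np.ceil(total * fs)) + 1
    t = np.arange(n) / fs
    v = np.zeros(n)
    for i in range(n_subpeaks):
        s = i * spacing
        m = (t >= s) & (t <= s + t_sub)
        v[m] += peak_velocity * np.sin(np.pi * (t[m] - s) / t_sub) ** 2
    return np.sign(amplitude) * v


def turn_duration(
    amplitude: float, peak_velocity: float, n_subpeaks: int = 1
) -> float:
    """Support duration (s) of the pulse :func:`make_turn_profile` builds."""
    t_sub = 2.0 * abs(amplitude) / (n_subpeaks * peak_velocity)
    return t_sub + (n_subpeaks - 1) * 0.6 * t_sub


def make_prescribed_segment(
    fs: float = 100.0,
    yaw_peak_dps: float = 80.0,
    pitch_peak_dps: float = 80.0,
    jump_peak_ms2: float = 15.0,
    peak_spacing_s: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment-frame (accel, gyro) arrays containing the prescribed
    shake / nod / jump calibration sequence.

    Defaults satisfy the detection criteria by construction: three yaw peaks
    > 40 deg/s, three pitch peaks > 40 deg/s, then three vertical
    acceleration-magnitude peaks > 10 m/s^2, successive peaks < 2 s apart.
    """
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz for the prescribed sequence")
    pulse_dur = 0.5
    jump_dur = 0.3
    pad = 1.0
    block = 2 * peak_spacing_s  # span of 3 peaks at given spacing
    gap = 1.0
    total = pad + (block + pulse_dur) + gap + (block + pulse_dur) + gap + (
        block + jump_dur
    ) + pad
    n = int(np.ceil(total * fs)) + 1
    t = np.arange(n) / fs
    gyro = np.zeros((n, 3))
    accel = np.zeros((n, 3))
    accel[:, 2] = -1.0

    def hann(center: float, dur: float) -> np.ndarray:
        m = np.abs(t - center) <= dur / 2
        w = np.zeros(n)
        w[m] = np.cos(np.pi * (t[m] - center) / dur) ** 2
        return w

    c0 = pad + pulse_dur / 2
    for i in range(3):  # shake: alternating yaw
        sign = 1 if i % 2 == 0 else -1
        gyro[:, 2] += sign * yaw_peak_dps * hann(c0 + i * peak_spacing_s, pulse_dur)
    c1 = c0 + block + pulse_dur / 2 + gap
    for i in range(3):  # nod: alternating pitch
        sign = 1 if i % 2 == 0 else -1
        gyro[:, 1] += sign * pitch_peak_dps * hann(c1 + i * peak_spacing_s, pulse_dur)
    c2 = c1 + block + pulse_dur / 2 + gap
    jump_g = jump_peak_ms2 / GRAVITY_MS2
    for i in range(3):  # jump: vertical accel magnitude peaks
        accel[:, 2] -= (jump_g - 1.0) * hann(c2 + i * peak_spacing_s, jump_dur)
    return accel, gyro


def make_gait_segment(
    n_steps: int,
    cadence: float = 2.0,
    fs: float = 100.0,
    impact_g: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Vertical-acceleration gait segment: ``n_steps`` impact minima on a
    -1 g gravity baseline, spaced ``1/cadence`` seconds.

    Each impact is a zero-mean waveform (a deep narrow dip of depth
    ``impact_g`` plus a wide shallow compensating lobe), so the segment mean
    stays exactly -1 g on the vertical axis — as for real gait, where cyclic
    components cancel over strides and only gravity remains. Returns
    ``(vertical_accel, step_times)``; step (initial-contact) times are the
    impact centres.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0.5 <= cadence <= 4.0:
        raise ValueError("cadence must lie in [0.5, 4] steps/s")
    impact_dur = min(0.15, 0.4 / cadence)
    pad = 0.5
    total = pad + n_steps / cadence + pad
    n = int(np.ceil(total * fs)) + 1
    t = np.arange(n) / fs
    va = np.full(n, -1.0)
    step_times = pad + (np.arange(n_steps) + 0.5) / cadence
    for c in step_times:
        m = np.abs(t - c) <= impact_dur / 2
        va[m] -= 2.0 * impact_g * np.cos(np.pi * (t[m] - c) / impact_dur) ** 2
        w = np.abs(t - c) <= impact_dur
        va[w] += impact_g * np.cos(np.pi * (t[w] - c) / (2 * impact_dur)) ** 2
    return va, step_times


def _place(dst: np.ndarray, src: np.ndarray, start_idx: int) -> None:
    """Add ``src`` into ``dst`` starting at ``start_idx`` (clipped)."""
    i0 = max(start_idx, 0)
    i1 = min(start_idx + src.size, dst.size)
    if i1 > i0:
        dst[i0:i1] += src[i0 - start_idx : i1 - start_idx]


def _validate_config(config: ScenarioConfig) -> None:
    dur = config.duration_s
    for site, scripts in config.turn_scripts.items():
        if site not in SITES:
            raise ValueError(f"unknown turn-script site {site!r}")
        spans = []
        for ts in scripts:
            end = ts.onset_time + turn_duration(
                ts.amplitude, ts.peak_velocity, ts.n_subpeaks
            )
            if ts.onset_time < 0 or end > dur:
                raise ValueError(
                    f"turn script at {ts.onset_time}s on {site} lies outside "
                    f"[0, {dur}]s"
                )
            spans.append((ts.onset_time, end))
        spans.sort()
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError(
                    f"overlapping turn scripts on {site} at {s0:.2f}s and {s1:.2f}s"
                )
    for s, e in config.nonwear_intervals:
        if not (0 <= s < e <= dur):
            raise ValueError(f"non-wear interval ({s}, {e}) outside [0, {dur}]")
        for site, scripts in config.turn_scripts.items():
            for ts in scripts:
                end = ts.onset_time + turn_duration(
                    ts.amplitude, ts.peak_velocity, ts.n_subpeaks
                )
                if ts.onset_time < e and end > s:
                    raise ValueError(
                        f"turn script at {ts.onset_time}s on {site} overlaps "
                        f"non-wear interval ({s}, {e})"
                    )


def simulate_recording(
    config: ScenarioConfig,
) -> tuple[dict[str, ImuRecording], GroundTruth]:
    """Generate one recording per site plus the scripted ground truth.

    Deterministic given ``config.seed``. Mounting rotations are applied to
    the segment-frame truth; gravity is present on the accelerometer;
    non-wear gaps contain zero angular rate and a frozen gravity vector with
    noise below the activity-count floor.
    """
    _validate_config(config)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    truth = GroundTruth(
        true_nonwear=[tuple(iv) for iv in config.nonwear_intervals],
        true_mounting={
            s: tuple(config.mounting_rotation.get(s, (0.0, 0.0, 0.0))) for s in SITES
        },
    )
    gyro = {s: np.zeros((n, 3)) for s in SITES}
    accel = {s: np.zeros((n, 3)) for s in SITES}
    for s in SITES:
        accel[s][:, 2] = -1.0

    # --- scripted turns -------------------------------------------------
    for site in SITES:
        for ts in config.turn_scripts.get(site, []):
            pulse = make_turn_profile(
                ts.amplitude, ts.peak_velocity, ts.n_subpeaks, fs
            )
            i0 = int(round(ts.onset_time * fs))
            end = ts.onset_time + pulse.size / fs
            direction = int(np.sign(ts.amplitude))
            c = ts.segment_coupling
            _place(gyro[site][:, 2], pulse, i0)
            truth.true_turns.append(
                TrueTurn(site, ts.onset_time, end, ts.amplitude, direction)
            )
            if site == "head":
                if c > 0:
                    _place(gyro["lumbar"][:, 2], c * pulse, i0)
                    truth.true_turns.append(
                        TrueTurn("lumbar", ts.onset_time, end, c * ts.amplitude,
                                 direction)
                    )
                if c < 1:
                    truth.true_turns.append(
                        TrueTurn(
                            "head_on_body", ts.onset_time, end,
                            (1 - c) * ts.amplitude, direction, klass="volitional",
                        )
                    )
            elif site == "lumbar":
                if c > 0:
                    _place(gyro["head"][:, 2], c * pulse, i0)
                    truth.true_turns.append(
                        TrueTurn("head", ts.onset_time, end, c * ts.amplitude,
                                 direction)
                    )
                if c < 1:
                    truth.true_turns.append(
                        TrueTurn(
                            "head_on_body", ts.onset_time, end,
                            (c - 1) * ts.amplitude, -direction, klass="stabilizing",
                        )
                    )
    truth.true_turns.sort(key=lambda t: (t.site, t.start))

    # --- gait ------------------------------------------------------------
    for bout in config.gait_bouts:
        va, steps = make_gait_segment(bout.n_steps, bout.cadence, fs, bout.impact_g)
        impacts = va - (-1.0)
        i0 = int(round(bout.start * fs))
        _place(accel["lumbar"][:, 2], impacts, i0)
        _place(accel["thoracic"][:, 2], 0.5 * impacts, i0)
        _place(accel["head"][:, 2], 0.3 * impacts, i0)
        truth.true_steps.extend((bout.start + steps).tolist())
    truth.true_steps.sort()

    # --- prescribed calibration sequences (head sensor) ------------------
    for t0 in config.prescribed_movement_times:
        pa, pg = make_prescribed_segment(fs)
        i0 = int(round(t0 * fs))
        _place(accel["head"][:, 2], pa[:, 2] - (-1.0), i0)
        for j in range(3):
            _place(gyro["head"][:, j], pg[:, j], i0)

    # --- non-wear gaps ----------------------------------------------------
    nonwear_mask = np.zeros(n, dtype=bool)
    for s, e in config.nonwear_intervals:
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        nonwear_mask[i0:i1] = True
    for site in SITES:
        gyro[site][nonwear_mask] = 0.0
        accel[site][nonwear_mask] = [0.0, 0.0, -1.0]

    # --- mounting rotation + noise ---------------------------------------
    rng = np.random.default_rng(config.seed)
    recordings: dict[str, ImuRecording] = {}
    time_s = np.arange(n) / fs
    for site in SITES:
        C = euler_zyx(*truth.true_mounting[site])
        g_sensor = gyro[site] @ C.T
        a_sensor = accel[site] @ C.T
        g_noise = rng.normal(0.0, config.gyro_noise_sd, size=(n, 3))
        a_noise = rng.normal(0.0, config.accel_noise_sd, size=(n, 3))
        g_noise[nonwear_mask] = 0.0
        if config.accel_noise_sd > 0:
            a_noise[nonwear_mask] *= NONWEAR_ACCEL_NOISE_SD / config.accel_noise_sd
        recordings[site] = ImuRecording(
            time_s=time_s,
            accel=a_sensor + a_noise,
            gyro=g_sensor + g_noise,
            fs=fs,
            site=site,
            frame="sensor",
            start_epoch=config.start_epoch,
        )
    return recordings, truth
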