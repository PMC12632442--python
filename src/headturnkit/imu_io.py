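"""Raw IMU ingestion: CSV reading/writing, sampling regularisation, tap-based
synchronisation and calendar-day segmentation.

Recordings are tri-axial accelerometer (g) + tri-axial gyroscope (deg/s)
streams, nominally 100 Hz, from up to three sites (head, thoracic, lumbar).
The CSV contract is a header ``time_s,ax_g,ay_g,az_g,gx_dps,gy_dps,gz_dps``;
columns are matched by name, not position.
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

CSV_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps"]
SITES = ("head", "thoracic", "lumbar")

ACCEL_RANGE_G = 8.0
GYRO_RANGE_DPS = 2000.0


@dataclass
class ImuRecording:
    """One sensor site's accelerometer + gyroscope stream.

    ``time_s`` is seconds relative to ``start_epoch`` (seconds since the Unix
    epoch, UTC). After :func:`regularize_sampling` the timestamps form a
    strict uniform grid at ``fs``. ``frame`` is ``"sensor"`` for raw data and
    ``"segment"`` once an alignment transform has been applied.
    """

    time_s: np.ndarray
    accel: np.ndarray  # (T, 3) in g
    gyro: np.ndarray  # (T, 3) in deg/s
    fs: float = 100.0
    site: str = "head"
    frame: str = "sensor"
    start_epoch: float = 0.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.shape != (self.time_s.size, 3):
            raise ValueError(
                f"accel shape {self.accel.shape} does not match "
                f"{self.time_s.size} timestamps"
            )
        if self.gyro.shape != self.accel.shape:
            raise ValueError("accel and gyro must have equal length")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.frame not in ("sensor", "segment"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.accel.size and np.nanmax(np.abs(self.accel)) > ACCEL_RANGE_G:
            raise ValueError(f"acceleration exceeds +/-{ACCEL_RANGE_G} g range")
        if self.gyro.size and np.nanmax(np.abs(self.gyro)) > GYRO_RANGE_DPS:
            raise ValueError(f"angular rate exceeds +/-{GYRO_RANGE_DPS} deg/s range")

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.time_s[-1] - self.time_s[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        if self.n_samples < 2:
            return True
        grid = self.time_s[0] + np.arange(self.n_samples) / self.fs
        return bool(np.allclose(self.time_s, grid, atol=rtol / self.fs))

    def copy(self) -> "ImuRecording":
        return dataclasses.replace(
            self,
            time_s=self.time_s.copy(),
            accel=self.accel.copy(),
            gyro=self.gyro.copy(),
        )


@dataclass
class DaySegment:
    """Half-open sample range of one local calendar day, [00:00, 24:00)."""

    date: datetime.date
    start_index: int
    stop_index: int
    partial: bool = False

    @property
    def sample_range(self) -> tuple[int, int]:
        return (self.start_index, self.stop_index)


def read_recording(
    path: str | Path,
    site: str,
    fs: float = 100.0,
    start_epoch: float = 0.0,
) -> ImuRecording:
    """Read a raw recording from CSV (header-keyed; column order is free).

    Raises ``ValueError`` on missing columns, non-monotone timestamps (the
    first offending row is named) or when more than 10% of the sampling
    intervals are gaps (> 1.5x the median interval).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.nonzero(dt < 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: time goes backwards at row {int(bad[0]) + 1} "
            f"(time_s {t[bad[0]]} -> {t[bad[0] + 1]})"
        )
    if dt.size:
        med = np.median(dt[dt > 0]) if np.any(dt > 0) else 0.0
        if med > 0:
            gap_frac = float(np.mean(dt > 1.5 * med))
            if gap_frac > 0.10:
                raise ValueError(
                    f"{path}: {gap_frac:.0%} of sampling intervals are gaps "
                    "(>1.5x median); recording rejected"
                )
    accel = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    gyro = df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(dtype=float)
    return ImuRecording(
        time_s=t, accel=accel, gyro=gyro, fs=fs, site=site, start_epoch=start_epoch
    )


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording in the package CSV dialect (round-trips bit-exactly)."""
    df = pd.DataFrame(
        {
            "time_s": rec.time_s,
            "ax_g": rec.accel[:, 0],
            "ay_g": rec.accel[:, 1],
            "az_g": rec.accel[:, 2],
            "gx_dps": rec.gyro[:, 0],
            "gy_dps": rec.gyro[:, 1],
            "gz_dps": rec.gyro[:, 2],
        }
    )
    df.to_csv(path, index=False)


def regularize_sampling(rec: ImuRecording, fs: float = 100.0) -> ImuRecording:
    """Collapse duplicate timestamps (first kept) and linearly interpolate all
    channels onto the uniform ``fs`` grid spanning [first, last] timestamp.

    Already-uniform input at the target rate is returned unchanged, which
    makes the operation idempotent.
    """
    t = rec.time_s
    uniq, first_idx = np.unique(t, return_index=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct timestamps to regularize")
    if rec.fs == fs and uniq.size == t.size and rec.is_uniform():
        return rec.copy()
    n = int(np.floor((uniq[-1] - uniq[0]) * fs + 0.5)) + 1
    grid = uniq[0] + np.arange(n) / fs
    accel = np.column_stack(
        [np.interp(grid, uniq, rec.accel[first_idx, j]) for j in range(3)]
    )
    gyro = np.column_stack(
        [np.interp(grid, uniq, rec.gyro[first_idx, j]) for j in range(3)]
    )
    return ImuRecording(
        time_s=grid,
        accel=accel,
        gyro=gyro,
        fs=fs,
        site=rec.site,
        frame=rec.frame,
        start_epoch=rec.start_epoch,
    )


def synchronize(
    recordings: Sequence[ImuRecording],
    tap_window: tuple[float, float],
    min_correlation: float = 0.5,
) -> list[int]:
    """Integer sample offsets aligning each recording to the first one.

    The three synchronisation taps produce large vertical-acceleration
    transients; cross-correlating the vertical channel inside ``tap_window``
    gives each site's lag relative to the reference (offset 0). A positive
    offset means the recording lags the reference by that many samples.

    If the correlation peak is not unique or its normalized value falls below
    ``min_correlation``, a warning is issued and offset 0 is returned for
    that recording.
    """
    start, end = tap_window
    if end - start > 60.0 + 1e-9:
        raise ValueError("tap window must be at most 60 s")

    def window_vertical(rec: ImuRecording) -> np.ndarray:
        m = (rec.time_s >= start) & (rec.time_s < end)
        if not np.any(m):
            raise ValueError(f"recording ({rec.site}) does not contain the tap window")
        x = rec.accel[m, 2]
        return x - x.mean()

    ref = window_vertical(recordings[0])
    offsets = [0]
    from scipy.signal import correlate

    for rec in recordings[1:]:
        x = window_vertical(rec)
        c = correlate(x, ref, mode="full")
        lags = np.arange(-(ref.size - 1), x.size)
        denom = np.linalg.norm(x) * np.linalg.norm(ref)
        if denom == 0:
            warnings.warn(
                f"synchronize: zero-energy tap window for {rec.site}; offset 0"
            )
            offsets.append(0)
            continue
        cn = c / denom
        best = int(np.argmax(cn))
        peak = float(cn[best])
        near = np.nonzero(cn > 0.98 * peak)[0]
        ambiguous = bool(np.any(np.abs(near - best) > 2))
        if peak < min_correlation or ambiguous:
            warnings.warn(
                f"synchronize: unreliable correlation for {rec.site} "
                f"(peak {peak:.2f}, ambiguous={ambiguous}); offset 0"
            )
            offsets.append(0)
        else:
            offsets.append(int(lags[best]))
    return offsets


def apply_offset(rec: ImuRecording, offset_samples: int) -> ImuRecording:
    """Shift a recording's time base by ``-offset_samples/fs`` so that a
    recording lagging the reference by ``offset_samples`` becomes aligned."""
    out = rec.copy()
    out.time_s = out.time_s - offset_samples / rec.fs
    return out


def correct_drift(
    rec: ImuRecording,
    pre_anchor: tuple[float, float],
    post_anchor: tuple[float, float],
) -> ImuRecording:
    """Piecewise-linear clock-drift correction between two tap anchors.

    Each anchor is ``(measured_time_s, reference_time_s)``. Sample times are
    linearly rescaled so the anchors land on their reference times, then the
    signal is re-interpolated onto the uniform grid. Device clocks drift on
    the order of seconds per day; the correction form (linear) is a package
    decision.
    """
    (m0, r0), (m1, r1) = pre_anchor, post_anchor
    if m1 <= m0:
        raise ValueError("anchors must be in increasing measured time")
    scale = (r1 - r0) / (m1 - m0)
    out = rec.copy()
    out.time_s = r0 + (rec.time_s - m0) * scale
    return regularize_sampling(out, fs=rec.fs)


def segment_days(rec: ImuRecording, timezone: str) -> list[DaySegment]:
    """Split a recording into local calendar days, [00:00:00, 24:00:00).

    A sample falling exactly on midnight belongs to the new day. First/last
    days that do not span the full day are flagged ``partial``.
    """
    if rec.n_samples == 0:
        return []
    tz = ZoneInfo(timezone)
    abs_t = rec.start_epoch + rec.time_s

    def local_midnight_epoch(d: datetime.date) -> float:
        return datetime.datetime(d.year, d.month, d.day, tzinfo=tz).timestamp()

    first_local = datetime.datetime.fromtimestamp(abs_t[0], tz)
    day = first_local.date()
    segments: list[DaySegment] = []
    start_idx = 0
    while start_idx < rec.n_samples:
        next_day = day + datetime.timedelta(days=1)
        boundary = local_midnight_epoch(next_day)
        stop_idx = int(np.searchsorted(abs_t, boundary, side="left"))
        covers_start = abs_t[start_idx] <= local_midnight_epoch(day) + 0.5 / rec.fs
        covers_end = (
            stop_idx < rec.n_samples
            or abs_t[-1] >= boundary - 1.5 / rec.fs
        )
        segments.append(
            DaySegment(
                date=day,
                start_index=start_idx,
                stop_index=stop_idx,
                partial=not (covers_start and covers_end),
            )
        )
        start_idx = stop_idx
        day = next_day
    return segments
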