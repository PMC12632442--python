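"""Discrete turn detection from vertical-axis angular velocity.

The detector is a two-filter scheme. The yaw angular-velocity signal is
smoothed by a zero-phase FIR filter whose impulse response is an
Epanechnikov (parabolic) kernel of 1.476 s; rectified local maxima of this
heavily smoothed signal above 15 deg/s mark candidate turns. A lighter
0.383 s Epanechnikov FIR locates each turn's start and end as the nearest
crossings below 5 deg/s around the peak. The raw (unfiltered) aligned
signal between those boundaries is integrated to give the turn amplitude;
its sign gives the direction, its absolute maximum the peak velocity.

Jerky, multi-peaked turns are consolidated by an iterative merge pass:
sub-10-degree candidates within 1/3 s of a same-direction neighbour are
merged (re-integrated over the union) until no eligible pair remains or a
merged turn would exceed 10 s. Remaining turns under 10 degrees are
discarded. Turns are classed small (< 45 deg) or large (>= 45 deg).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import find_peaks


@dataclass
class TurnParams:
    """Detector parameters; defaults are the published values."""

    main_filter_duration: float = 1.476  # s
    boundary_filter_duration: float = 0.383  # s
    peak_threshold: float = 15.0  # deg/s
    boundary_threshold: float = 5.0  # deg/s
    merge_gap: float = 1.0 / 3.0  # s
    min_amplitude: float = 10.0  # deg
    max_merged_duration: float = 10.0  # s
    small_large_split: float = 45.0  # deg
    boundary_search_cap: float = 5.0  # s either side of a peak
    #: integrate/peak on the unfiltered aligned signal (True) or the
    #: boundary-filtered signal (False)
    use_unfiltered_amplitude: bool = True

    def __post_init__(self) -> None:
        for name in (
            "main_filter_duration",
            "boundary_filter_duration",
            "peak_threshold",
            "boundary_threshold",
            "merge_gap",
            "min_amplitude",
            "max_merged_duration",
            "small_large_split",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.boundary_threshold >= self.peak_threshold:
            raise ValueError("boundary_threshold must be below peak_threshold")


@dataclass
class TurnEvent:
    """One detected turn."""

    start: float  # s
    end: float  # s
    direction: int  # +1 / -1
    amplitude: float  # deg, magnitude
    peak_velocity: float  # deg/s, magnitude
    source: str = "head"  # head | thoracic | lumbar | head_on_body
    merged_from: int = 1

    @property
    def duration(self) -> float:
        return self.end - self.start


def epanechnikov_kernel(duration: float, fs: float) -> np.ndarray:
    """Unit-sum Epanechnikov kernel k(u) ~ (1 - u^2)+ on an odd-length
    support of round-to-odd(duration * fs) samples."""
    n = int(round(duration * fs))
    if n % 2 == 0:
        n -= 1  # round to odd, shorter side (1.476 s at 100 Hz -> 147 taps)
    if n < 3:
        raise ValueError("kernel support must be at least 3 samples")
    half = (n - 1) // 2
    u = (np.arange(n) - half) / (half + 1)
    k = 1.0 - u**2
    return k / k.sum()


def epanechnikov_fir(signal: np.ndarray, duration: float, fs: float) -> np.ndarray:
    """Zero-phase Epanechnikov FIR smoothing with reflected edges."""
    k = epanechnikov_kernel(duration, fs)
    return convolve1d(np.asarray(signal, dtype=float), k, mode="reflect")


def _boundary(below: np.ndarray, peak_idx: int, cap: int) -> tuple[int, int]:
    """Last below-threshold index before the peak and first after (capped)."""
    lo = max(0, peak_idx - cap)
    hi = min(below.size - 1, peak_idx + cap)
    before = np.nonzero(below[lo : peak_idx + 1])[0]
    start = lo + before[-1] if before.size else lo
    after = np.nonzero(below[peak_idx : hi + 1])[0]
    end = peak_idx + after[0] if after.size else hi
    return int(start), int(end)


def _measure(
    yaw: np.ndarray, fs: float, i0: int, i1: int
) -> tuple[float, int, float]:
    """(amplitude magnitude, direction, peak velocity) over samples [i0, i1]."""
    seg = yaw[i0 : i1 + 1]
    integral = float(np.trapezoid(seg, dx=1.0 / fs))
    direction = 1 if integral >= 0 else -1
    return abs(integral), direction, float(np.max(np.abs(seg))) if seg.size else 0.0


def detect_turns(
    yaw: np.ndarray,
    fs: float,
    params: TurnParams | None = None,
    t0: float = 0.0,
    source: str = "head",
) -> list[TurnEvent]:
    """Detect turns in a segment-frame vertical angular-velocity series.

    ``t0`` is the time of the first sample; event times are reported on that
    clock. Returns events sorted by start time.
    """
    params = params or TurnParams()
    yaw = np.asarray(yaw, dtype=float)
    if yaw.size < 3:
        return []
    main = np.abs(epanechnikov_fir(yaw, params.main_filter_duration, fs))
    bound = np.abs(epanechnikov_fir(yaw, params.boundary_filter_duration, fs))
    peaks, _ = find_peaks(main, height=params.peak_threshold)
    if peaks.size == 0:
        return []
    below = bound < params.boundary_threshold
    cap = int(round(params.boundary_search_cap * fs))
    intervals = [_boundary(below, int(p), cap) for p in peaks]

    # candidates sharing/overlapping boundary intervals collapse to one
    intervals.sort()
    merged_iv: list[list[int]] = []
    for i0, i1 in intervals:
        if merged_iv and i0 <= merged_iv[-1][1]:
            merged_iv[-1][1] = max(merged_iv[-1][1], i1)
        else:
            merged_iv.append([i0, i1])

    basis = yaw if params.use_unfiltered_amplitude else bound * np.sign(yaw)
    candidates = []
    for i0, i1 in merged_iv:
        amp, direction, pk = _measure(basis, fs, i0, i1)
        candidates.append(
            TurnEvent(
                start=t0 + i0 / fs,
                end=t0 + i1 / fs,
                direction=direction,
                amplitude=amp,
                peak_velocity=pk,
                source=source,
            )
        )
    return merge_turns(candidates, params, yaw=yaw, fs=fs, t0=t0)


def merge_turns(
    candidates: list[TurnEvent],
    params: TurnParams | None = None,
    yaw: np.ndarray | None = None,
    fs: float | None = None,
    t0: float = 0.0,
) -> list[TurnEvent]:
    """Iteratively consolidate jerky turns, then discard sub-threshold ones.

    A candidate with amplitude below ``min_amplitude`` whose gap to a
    same-direction neighbour is under ``merge_gap`` is merged with it: the
    interval becomes the union, the amplitude is re-integrated over the
    union when the signal is available (summed otherwise), the peak is the
    maximum of the members. Merging stops when no eligible pair remains or
    when the union would exceed ``max_merged_duration``. Opposite-direction
    neighbours never merge. Finally, turns with amplitude under
    ``min_amplitude`` are dropped.
    """
    params = params or TurnParams()
    events = sorted((dataclasses.replace(e) for e in candidates), key=lambda e: e.start)

    def remeasure(a: TurnEvent, b: TurnEvent) -> TurnEvent:
        merged = TurnEvent(
            start=a.start,
            end=b.end,
            direction=a.direction,
            amplitude=a.amplitude + b.amplitude,
            peak_velocity=max(a.peak_velocity, b.peak_velocity),
            source=a.source,
            merged_from=a.merged_from + b.merged_from,
        )
        if yaw is not None and fs is not None:
            i0 = int(round((a.start - t0) * fs))
            i1 = min(int(round((b.end - t0) * fs)), yaw.size - 1)
            amp, direction, pk = _measure(yaw, fs, i0, i1)
            merged.amplitude = amp
            merged.direction = direction
            merged.peak_velocity = pk
        return merged

    changed = True
    while changed:
        changed = False
        for i in range(len(events) - 1):
            a, b = events[i], events[i + 1]
            if a.direction != b.direction:
                continue
            gap = b.start - a.end
            if gap >= params.merge_gap:
                continue
            if min(a.amplitude, b.amplitude) >= params.min_amplitude:
                continue  # only sub-threshold turns trigger consolidation
            if b.end - a.start > params.max_merged_duration:
                continue
            events[i : i + 2] = [remeasure(a, b)]
            changed = True
            break
    return [e for e in events if e.amplitude >= params.min_amplitude]


def classify_size(turn: TurnEvent, params: TurnParams | None = None) -> str:
    """'small' for amplitude < 45 deg, 'large' otherwise (45 deg is large)."""
    params = params or TurnParams()
    return "small" if turn.amplitude < params.small_large_split else "large"
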