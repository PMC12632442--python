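"""Head-on-body turns: detection from the head-minus-lumbar differential
yaw velocity, and volitional vs stabilizing classification.

Once both sensors are aligned with their segments' superior-inferior axes,
the samplewise difference of head and lumbar yaw angular velocity isolates
head rotation relative to the trunk. The standard turn detector applied to
that differential signal yields head-on-body turns. Each is classified by
comparing peak in-space magnitudes over the turn interval: **volitional**
when the head rotates faster in space than the trunk (gaze reorientation),
**stabilizing** otherwise (gaze held while the trunk turns). Ties break to
stabilizing, since volitional is defined by a strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imu_io import ImuRecording
from .turndetect import TurnEvent, TurnParams, detect_turns


@dataclass
class ClassifiedTurn:
    """A head-on-body turn with its volitional/stabilizing label."""

    turn: TurnEvent
    klass: str  # volitional | stabilizing
    head_peak_in_space: float  # deg/s
    lumbar_peak_in_space: float  # deg/s


def _check_grids(head: ImuRecording, lumbar: ImuRecording) -> None:
    if head.frame != "segment" or lumbar.frame != "segment":
        raise ValueError("head and lumbar recordings must be segment-frame")
    if head.n_samples != lumbar.n_samples or head.fs != lumbar.fs:
        raise ValueError("head and lumbar recordings are on different grids")
    if not np.allclose(head.time_s, lumbar.time_s, atol=0.5 / head.fs):
        raise ValueError("head and lumbar recordings are not synchronized")


def differential_yaw(head: ImuRecording, lumbar: ImuRecording) -> np.ndarray:
    """Samplewise head yaw minus lumbar yaw (deg/s)."""
    _check_grids(head, lumbar)
    return head.gyro[:, 2] - lumbar.gyro[:, 2]


def detect_hob_turns(
    head: ImuRecording,
    lumbar: ImuRecording,
    params: TurnParams | None = None,
) -> list[ClassifiedTurn]:
    """Detect and classify head-on-body turns.

    The turn detector runs on the differential yaw signal; for each turn the
    peak in-space magnitudes of head and lumbar yaw are measured over the
    turn interval (boundary samples included).
    """
    params = params or TurnParams()
    diff = differential_yaw(head, lumbar)
    t0 = float(head.time_s[0])
    fs = head.fs
    turns = detect_turns(diff, fs, params, t0=t0, source="head_on_body")
    out: list[ClassifiedTurn] = []
    for ev in turns:
        i0 = max(0, int(round((ev.start - t0) * fs)))
        i1 = min(head.n_samples - 1, int(round((ev.end - t0) * fs)))
        hp = float(np.max(np.abs(head.gyro[i0 : i1 + 1, 2])))
        lp = float(np.max(np.abs(lumbar.gyro[i0 : i1 + 1, 2])))
        klass = "volitional" if hp > lp else "stabilizing"
        out.append(
            ClassifiedTurn(
                turn=ev,
                klass=klass,
                head_peak_in_space=hp,
                lumbar_peak_in_space=lp,
            )
        )
    return out


def hob_fraction(
    head_turns: list[TurnEvent], hob_turns: list
) -> tuple[float, bool]:
    """Proportion of head turns occurring independently of the trunk.

    Returns ``(fraction, flagged)``. The raw ratio can exceed 1 (the two
    counts come from different signals); values above 1 are reported clipped
    with ``flagged=True``. Zero head turns also sets the flag (undefined
    ratio, reported as 0).
    """
    n_head = len(head_turns)
    n_hob = len(hob_turns)
    if n_head == 0:
        return 0.0, True
    frac = n_hob / n_head
    if frac > 1.0:
        return 1.0, True
    return frac, False
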