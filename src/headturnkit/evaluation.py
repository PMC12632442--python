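"""Ground-truth evaluation utilities for synthetic scenarios.

Matches detected turn events against scripted truth by interval overlap and
derives recall / precision / amplitude-error summaries. Used by the test
suite and the end-to-end evaluation script; not part of the measurement
pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthgen import TrueTurn
from .turndetect import TurnEvent


@dataclass
class MatchResult:
    pairs: list[tuple[TrueTurn, TurnEvent]]
    missed: list[TrueTurn]
    spurious: list[TurnEvent]

    @property
    def recall(self) -> float:
        denom = len(self.pairs) + len(self.missed)
        return len(self.pairs) / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        denom = len(self.pairs) + len(self.spurious)
        return len(self.pairs) / denom if denom else float("nan")

    def relative_amplitude_errors(self) -> np.ndarray:
        """Signed (detected - true)/true amplitude errors over matched pairs."""
        return np.array(
            [
                (d.amplitude - abs(t.amplitude)) / abs(t.amplitude)
                for t, d in self.pairs
            ]
        )


def match_turns(
    true_turns: list[TrueTurn], detected: list[TurnEvent]
) -> MatchResult:
    """Greedy one-to-one matching of detected events to scripted turns by
    interval overlap (largest overlap wins)."""
    remaining = list(detected)
    pairs: list[tuple[TrueTurn, TurnEvent]] = []
    missed: list[TrueTurn] = []
    for t in sorted(true_turns, key=lambda x: x.start):
        best = None
        best_ov = 0.0
        for d in remaining:
            ov = min(t.end, d.end) - max(t.start, d.start)
            if ov > best_ov:
                best, best_ov = d, ov
        if best is None:
            missed.append(t)
        else:
            pairs.append((t, best))
            remaining.remove(best)
    return MatchResult(pairs=pairs, missed=missed, spurious=remaining)


def match_times(
    true_times: np.ndarray, detected_times: np.ndarray, tol_s: float = 0.25
) -> tuple[int, int, int]:
    """(TP, FN, FP) matching point events within ``tol_s`` (one-to-one)."""
    true_times = np.sort(np.asarray(true_times, dtype=float))
    det = sorted(np.asarray(detected_times, dtype=float).tolist())
    tp = 0
    for t in true_times:
        for i, d in enumerate(det):
            if abs(d - t) <= tol_s:
                tp += 1
                det.pop(i)
                break
    fn = true_times.size - tp
    fp = len(det)
    return tp, fn, fp


def f1_score(tp: int, fn: int, fp: int) -> float:
    denom = 2 * tp + fn + fp
    return 2 * tp / denom if denom else float("nan")
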