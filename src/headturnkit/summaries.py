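"""Per-day aggregation, descriptive statistics, and multi-day reliability.

Day summaries collect turn counts (by source and by small/large size
class), mean amplitudes and peak velocities, head-on-body counts by class,
step counts and wear hours; a day is *valid* when the device was worn at
least 10 hours. Cohort descriptives use the coefficient of variation
(CV = SD/mean) pooled over each subject's per-turn values.

Reliability of k-day averages uses the intraclass correlation ICC(2,k):
two-way model, average measures. The default form is *consistency*,
ICC = (MS_rows - MS_error) / MS_rows from the two-way ANOVA decomposition;
the *agreement* form (which penalises day-to-day mean shifts) is also
available. Subset reliability pairs each subject's k-day mean (over all
C(5, k) subsets of their first five valid days) with their 5-day mean and
averages the resulting ICCs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import WalkingBout, WearInterval, daily_wear_hours
from .hob import ClassifiedTurn
from .turndetect import TurnEvent, TurnParams, classify_size

VALID_DAY_WEAR_HOURS = 10.0


@dataclass
class DaySummary:
    """Per-subject per-day aggregates."""

    subject: str = ""
    date: object = None
    wear_hours: float = 0.0
    n_turns: int = 0
    n_small: int = 0
    n_large: int = 0
    mean_amplitude: float = float("nan")
    mean_peak_velocity: float = float("nan")
    small_mean_amplitude: float = float("nan")
    small_mean_peak_velocity: float = float("nan")
    large_mean_amplitude: float = float("nan")
    large_mean_peak_velocity: float = float("nan")
    n_steps: int = 0
    n_hob: int = 0
    n_volitional: int = 0
    n_stabilizing: int = 0
    valid: bool = False


def _mean(values: list[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def summarize_day(
    turns: list[TurnEvent],
    hob_turns: list[ClassifiedTurn],
    bouts: list[WalkingBout],
    wear_intervals: list[WearInterval],
    subject: str = "",
    date: object = None,
    params: TurnParams | None = None,
) -> DaySummary:
    """Aggregate one subject-day of detector outputs.

    Mean fields are NaN (undefined) when the corresponding turn list is
    empty. ``n_steps`` counts only steps inside retained walking bouts.
    """
    params = params or TurnParams()
    small = [t for t in turns if classify_size(t, params) == "small"]
    large = [t for t in turns if classify_size(t, params) == "large"]
    wear_hours = daily_wear_hours(wear_intervals)
    return DaySummary(
        subject=subject,
        date=date,
        wear_hours=wear_hours,
        n_turns=len(turns),
        n_small=len(small),
        n_large=len(large),
        mean_amplitude=_mean([t.amplitude for t in turns]),
        mean_peak_velocity=_mean([t.peak_velocity for t in turns]),
        small_mean_amplitude=_mean([t.amplitude for t in small]),
        small_mean_peak_velocity=_mean([t.peak_velocity for t in small]),
        large_mean_amplitude=_mean([t.amplitude for t in large]),
        large_mean_peak_velocity=_mean([t.peak_velocity for t in large]),
        n_steps=sum(b.n_steps for b in bouts),
        n_hob=len(hob_turns),
        n_volitional=sum(1 for h in hob_turns if h.klass == "volitional"),
        n_stabilizing=sum(1 for h in hob_turns if h.klass == "stabilizing"),
        valid=wear_hours >= VALID_DAY_WEAR_HOURS,
    )


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """CV = sample SD / mean. Requires >= 2 values and a nonzero mean."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least 2 values")
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=ddof) / m)


def icc_2k(data: np.ndarray, form: str = "consistency") -> float:
    """Average-measures intraclass correlation from a subjects x measurements
    matrix (two-way model).

    ``form="consistency"``: (MS_rows - MS_error) / MS_rows.
    ``form="agreement"``: (MS_rows - MS_error) /
    (MS_rows + (MS_cols - MS_error) / n).

    Degenerate input with no between-subject variance returns 1.0 with a
    warning. No missing cells are allowed (listwise-delete beforehand).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 columns")
    if np.any(np.isnan(x)):
        raise ValueError("missing cells; listwise-delete before calling icc_2k")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0:
        warnings.warn("no between-subject variance; ICC set to 1.0 by convention")
        return 1.0
    if form == "consistency":
        return float((ms_rows - ms_err) / ms_rows)
    if form == "agreement":
        return float((ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n))
    raise ValueError(f"unknown ICC form {form!r}")


@dataclass
class ReliabilityResult:
    """ICC of k-day subset means against the full 5-day mean."""

    metric: str
    k: int
    icc: float
    n_subjects: int
    per_subset_icc: list[float] = field(default_factory=list)
    subset_policy: str = "all C(5,k) subsets, averaged"


def summaries_to_frame(summaries: list[DaySummary]) -> pd.DataFrame:
    """Tabular view of a list of day summaries."""
    return pd.DataFrame([vars(s) for s in summaries])


def subset_reliability(
    day_summaries: list[DaySummary] | pd.DataFrame,
    metric: str,
    k: int,
    n_days: int = 5,
    form: str = "consistency",
) -> ReliabilityResult:
    """Reliability of a k-day average of ``metric`` against the full
    ``n_days``-day average.

    Subjects must have at least ``n_days`` valid days (>= 10 h wear); the
    first ``n_days`` chronological valid days are used. For every k-subset
    of those days, each subject's subset mean is paired with their full
    mean and an ICC computed over the two-column matrix; the reported ICC
    is the average across subsets.
    """
    if not 1 <= k <= n_days:
        raise ValueError(f"k must lie in [1, {n_days}]")
    df = (
        day_summaries
        if isinstance(day_summaries, pd.DataFrame)
        else summaries_to_frame(day_summaries)
    )
    valid = df[df["valid"]].sort_values(["subject", "date"])
    rows = []
    for subject, grp in valid.groupby("subject"):
        if len(grp) < n_days:
            continue
        rows.append(grp[metric].to_numpy(dtype=float)[:n_days])
    if len(rows) < 2:
        raise ValueError(
            f"need >= 2 subjects with {n_days} valid days; got {len(rows)}"
        )
    mat = np.vstack(rows)  # subjects x n_days
    full_mean = mat.mean(axis=1)
    per_subset = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for combo in itertools.combinations(range(n_days), k):
            sub_mean = mat[:, combo].mean(axis=1)
            per_subset.append(icc_2k(np.column_stack([sub_mean, full_mean]), form))
    return ReliabilityResult(
        metric=metric,
        k=k,
        icc=float(np.mean(per_subset)),
        n_subjects=mat.shape[0],
        per_subset_icc=per_subset,
    )


def reliability_band(icc: float) -> str:
    """Interpretive band: <0.50 poor; [0.50, 0.75) moderate; [0.75, 0.90)
    good; >= 0.90 excellent."""
    if icc > 1.0:
        raise ValueError("ICC cannot exceed 1")
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "excellent"
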