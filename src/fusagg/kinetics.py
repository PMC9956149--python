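"""Time-course assembly, fold changes, plateau levels and rupture detection.

Works on tidy per-frame quantification tables (one row per frame with
``time_h``, ``condition``, ``replicate`` and metric columns such as
``aggregates_per_cell`` or ``total_fluorescence``), the CSV format written
by the quantification stage. Replicates are aggregated by their arithmetic
mean at each time point before ratios are taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourse",
    "RuptureEvent",
    "quant_frame_table",
    "fold_change_at",
    "plateau_level",
    "detect_ruptures",
    "summarize_timecourses",
]


@dataclass
class TimeCourse:
    """One replicate's ordered (time, metric) series for one condition."""

    condition: str
    replicate: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def at(self, time_h: float) -> float:
        """Metric value at ``time_h``; exact time points are returned as
        stored, otherwise linear interpolation between neighbours."""
        if time_h < self.times[0] or time_h > self.times[-1]:
            raise ValueError(f"time {time_h} outside course [{self.times[0]}, {self.times[-1]}]")
        exact = np.nonzero(self.times == time_h)[0]
        if exact.size:
            return float(self.values[exact[0]])
        return float(np.interp(time_h, self.times, self.values))


@dataclass(frozen=True)
class RuptureEvent:
    """A sudden drop between consecutive time points."""

    time_h: float
    drop_fraction: float  # in (0, 1]
    metric: str


def quant_frame_table(quants) -> pd.DataFrame:
    """Tidy DataFrame from an iterable of FrameQuant records."""
    return pd.DataFrame([vars(q) if not isinstance(q, dict) else q for q in quants])


def _courses(df: pd.DataFrame, condition: str, metric: str) -> list[TimeCourse]:
    sub = df[df["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no rows for condition {condition!r}")
    out = []
    for rep, grp in sub.groupby("replicate"):
        grp = grp.sort_values("time_h")
        out.append(
            TimeCourse(condition, str(rep), grp["time_h"].to_numpy(), grp[metric].to_numpy())
        )
    return out


def fold_change_at(
    df: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    time_h: float,
    metric: str = "aggregates_per_cell",
) -> float:
    """Ratio A/B of the replicate-mean metric at ``time_h``.

    Each replicate is evaluated at ``time_h`` (interpolating if needed),
    replicates are averaged per condition, then the ratio is formed.
    A zero denominator mean gives NaN (reported missing, not raised).
    """
    mean_a = float(np.mean([tc.at(time_h) for tc in _courses(df, condition_a, metric)]))
    mean_b = float(np.mean([tc.at(time_h) for tc in _courses(df, condition_b, metric)]))
    if mean_b == 0:
        return math.nan
    return mean_a / mean_b


def plateau_level(
    df: pd.DataFrame,
    condition: str,
    window_h: float = 5.0,
    metric: str = "aggregates_per_cell",
) -> tuple[float, float, int]:
    """Mean metric over the final ``window_h`` hours, per replicate, then
    summarised across replicates as (mean, sd, n)."""
    courses = _courses(df, condition, metric)
    t_end = max(tc.times[-1] for tc in courses)
    t_start = t_end - window_h
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    rep_means = []
    for tc in courses:
        in_window = tc.times >= t_start
        if not in_window.any():
            raise ValueError("plateau window contains no time points")
        rep_means.append(float(tc.values[in_window].mean()))
    arr = np.asarray(rep_means)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0, arr.size


def detect_ruptures(
    tc: TimeCourse,
    min_drop: float = 0.25,
    metric: str = "aggregates_per_cell",
) -> list[RuptureEvent]:
    """Saw-tooth drops: an event at every consecutive pair where the metric
    falls below ``(1 - min_drop)`` of its previous value.

    Purely ratio-based, hence invariant under uniform scaling of the metric.
    """
    if len(tc.times) < 2:
        raise ValueError("need at least 2 time points")
    if not (0.0 < min_drop <= 1.0):
        raise ValueError("min_drop must be in (0, 1]")
    events = []
    for t0, t1, v0, v1 in zip(tc.times, tc.times[1:], tc.values, tc.values[1:]):
        if v0 > 0 and v1 < (1.0 - min_drop) * v0:
            events.append(RuptureEvent(time_h=float(t1), drop_fraction=float(1.0 - v1 / v0), metric=metric))
    return events


def summarize_timecourses(
    df: pd.DataFrame, metric: str = "aggregates_per_cell"
) -> pd.DataFrame:
    """Per condition and time point: replicate mean, +-1 SD and n
    (the summary plotted as error bars)."""
    g = df.groupby(["condition", "time_h"])[metric]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="count")
    return out.reset_index()
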