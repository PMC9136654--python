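"""Scheduled-clinic-hour windows and the during/outside time decomposition.

A physician's "scheduled clinic hours" on a day are the union of
half-open intervals ``[visit.start - margin, visit.end + margin)`` over
that day's actual scheduled visits (default margin 30 minutes, capturing
preparatory and closing work around consecutive visits); overlapping or
touching expansions merge.  Every action's occupancy interval
``[timestamp, timestamp + duration)`` is then split into the part
intersecting the windows (during) and the remainder (outside).

Half-open convention: an event at a window's exact end instant is
outside.  This removes any double counting at boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClinicWindows", "build_windows", "segment_action", "segment_actions"]

DEFAULT_MARGIN_MINUTES = 30.0

_NS = 1e9


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping/touching [start, end) intervals (seconds)."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s: list[float] = []
    merged_e: list[float] = []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:  # touching intervals merge
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


@dataclass
class ClinicWindows:
    """Merged clinic-hour windows, per physician and per physician-day.

    ``by_physician`` maps physician_id to ``(starts, ends)`` arrays of
    merged half-open intervals in epoch seconds, spanning the whole study
    period (used for segmentation, so windows crossing midnight behave
    correctly).  ``per_day`` is a tidy frame (physician_id, date, n_visits,
    window_start, window_end) where each window is assigned to the start
    date of its earliest generating visit.
    """

    margin_minutes: float
    by_physician: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    per_day: pd.DataFrame = field(default_factory=pd.DataFrame)

    def intervals_for(self, physician_id: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0)
        return self.by_physician.get(str(physician_id), (empty, empty))

    def visit_dates(self, physician_id: str) -> set:
        if len(self.per_day) == 0:
            return set()
        sub = self.per_day[self.per_day["physician_id"] == str(physician_id)]
        return set(sub["date"])


def build_windows(visits: pd.DataFrame, margin_minutes: float = DEFAULT_MARGIN_MINUTES) -> ClinicWindows:
    """Construct merged clinic windows from scheduled visits.

    Each visit contributes ``[start - margin, end + margin)``; per
    physician, overlapping or touching contributions merge, so
    back-to-back visits yield one window.  A window generated by an
    evening visit may cross midnight; it belongs to the visit's start
    date.
    """
    if margin_minutes < 0:
        raise ValueError("margin must be non-negative")
    margin_s = margin_minutes * 60.0
    out = ClinicWindows(margin_minutes=margin_minutes)
    rows = []
    if len(visits):
        vs = visits.assign(
            _s=visits["start"].astype("int64") / _NS - margin_s,
            _e=visits["end"].astype("int64") / _NS + margin_s,
            _date=visits["start"].dt.date,
        )
        for pid, grp in vs.groupby("physician_id", sort=True):
            starts, ends = _merge_intervals(grp["_s"].to_numpy(), grp["_e"].to_numpy())
            out.by_physician[str(pid)] = (starts, ends)
            # assign each merged interval to the start date of its earliest visit
            idx = np.searchsorted(starts, np.sort(grp["_s"].to_numpy()), side="right") - 1
            first_visit_date = {}
            n_visits = {}
            order = np.argsort(grp["_s"].to_numpy(), kind="stable")
            for j, which in zip(order, idx):
                d = grp["_date"].iloc[j]
                if which not in first_visit_date or d < first_visit_date[which]:
                    first_visit_date[which] = d
                n_visits[which] = n_visits.get(which, 0) + 1
            for k in range(len(starts)):
                rows.append(
                    dict(
                        physician_id=str(pid),
                        date=first_visit_date[k],
                        n_visits=n_visits[k],
                        window_start=pd.Timestamp(starts[k], unit="s"),
                        window_end=pd.Timestamp(ends[k], unit="s"),
                    )
                )
    out.per_day = pd.DataFrame(rows, columns=["physician_id", "date", "n_visits", "window_start", "window_end"])
    return out


def _cumulative_window_time(starts: np.ndarray, ends: np.ndarray, x: np.ndarray) -> np.ndarray:
    """F(x) = total window time in (-inf, x), vectorized over x."""
    if len(starts) == 0:
        return np.zeros_like(np.asarray(x, dtype=float))
    lengths = ends - starts
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    i = np.searchsorted(starts, x, side="right")  # number of intervals starting before x
    full = cum[i]
    # subtract the not-yet-elapsed tail of the last started interval
    last_end = np.where(i > 0, ends[np.maximum(i - 1, 0)], 0.0)
    last_len = np.where(i > 0, lengths[np.maximum(i - 1, 0)], 0.0)
    tail = np.clip(last_end - x, 0.0, last_len)
    return full - np.where(i > 0, tail, 0.0)


def segment_actions(
    actions: pd.DataFrame,
    windows: ClinicWindows,
    straddle_policy: str = "proportional",
) -> pd.DataFrame:
    """Split each action's duration into during/outside seconds.

    Adds ``during_s``, ``outside_s`` and ``primary_segment`` columns.
    ``during_s`` is the length of ``[t, t + duration) ∩ windows``;
    ``outside_s`` the remainder, so the two always sum to the duration.
    ``primary_segment`` ("during"/"outside") is decided by the start
    timestamp alone and is what frequency counts use, keeping counts
    integral.  ``straddle_policy="start"`` instead assigns the whole
    duration to the start-timestamp segment.
    """
    if straddle_policy not in ("proportional", "start"):
        raise ValueError(f"unknown straddle policy {straddle_policy!r}")
    out = actions.copy()
    n = len(out)
    during = np.zeros(n)
    start_in = np.zeros(n, dtype=bool)
    if n:
        t_all = out["timestamp"].to_numpy(dtype="datetime64[ns]").astype("int64") / _NS
        d_all = out["duration_s"].to_numpy(dtype=float)
        uid = out["user_id"].to_numpy()
        for pid in np.unique(uid):
            starts, ends = windows.intervals_for(pid)
            mask = uid == pid
            if len(starts) == 0:
                continue
            t = t_all[mask]
            d = d_all[mask]
            f0 = _cumulative_window_time(starts, ends, t)
            f1 = _cumulative_window_time(starts, ends, t + d)
            during[mask] = np.clip(f1 - f0, 0.0, d)
            i = np.searchsorted(starts, t, side="right")
            start_in[mask] = (i > 0) & (t < ends[np.maximum(i - 1, 0)])
    out["primary_segment"] = np.where(start_in, "during", "outside")
    if straddle_policy == "start":
        during = np.where(start_in, out["duration_s"].to_numpy(dtype=float), 0.0)
    out["during_s"] = during
    out["outside_s"] = out["duration_s"].to_numpy(dtype=float) - during
    return out


def segment_action(
    timestamp: pd.Timestamp,
    duration_s: float,
    windows: ClinicWindows,
    physician_id: str,
    straddle_policy: str = "proportional",
) -> tuple[float, float, str]:
    """Single-action convenience wrapper; returns (during_s, outside_s, primary_segment)."""
    df = pd.DataFrame(
        {"user_id": [str(physician_id)], "timestamp": [pd.Timestamp(timestamp)], "duration_s": [float(duration_s)]}
    )
    seg = segment_actions(df, windows, straddle_policy=straddle_policy)
    return float(seg["during_s"].iloc[0]), float(seg["outside_s"].iloc[0]), str(seg["primary_segment"].iloc[0])
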