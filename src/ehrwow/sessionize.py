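"""Per-action access-time estimation from inter-event deltas.

The audit log records instants, not durations.  Following the standard
inter-event-delta algorithm, the time attributed to an action is the gap
to the same user's next logged action; a user's final action gets zero.
Gaps longer than the idle cutoff (default 15 minutes) are treated as idle
time rather than active use and are removed.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

__all__ = ["estimate_access_time", "filter_idle"]

logger = logging.getLogger(__name__)

DEFAULT_IDLE_CUTOFF_MINUTES = 15.0


def estimate_access_time(
    events: pd.DataFrame,
    idle_cutoff_minutes: float = DEFAULT_IDLE_CUTOFF_MINUTES,
) -> pd.DataFrame:
    """Attach ``duration_s`` (gap to the same user's next event) and ``idle_flag``.

    ``events`` must be sorted by ``(user_id, timestamp)`` (the
    :func:`ehrwow.io_schemas.read_access_log` contract); deltas are computed
    strictly within user, and each user's last event gets duration 0.
    Deltas are taken across day boundaries — the idle filter subsequently
    removes overnight gaps.  ``idle_flag`` marks durations strictly above
    the cutoff; :func:`filter_idle` acts on the durations themselves.
    """
    out = events.copy()
    if len(out) == 0:
        out["duration_s"] = pd.Series(dtype=float)
        out["idle_flag"] = pd.Series(dtype=bool)
        return out
    ts = out["timestamp"].to_numpy(dtype="datetime64[ns]").astype("int64")
    uid = out["user_id"].to_numpy()
    same_user = uid[:-1] == uid[1:]
    deltas = np.diff(ts) / 1e9
    if np.any(deltas[same_user] < 0):
        raise ValueError("events are not sorted by (user_id, timestamp); re-read via read_access_log")
    duration = np.zeros(len(out))
    duration[:-1] = np.where(same_user, deltas, 0.0)
    out["duration_s"] = duration
    out["idle_flag"] = duration > idle_cutoff_minutes * 60.0
    return out


def filter_idle(
    actions: pd.DataFrame,
    cutoff_minutes: float = DEFAULT_IDLE_CUTOFF_MINUTES,
    policy: str = "drop",
) -> tuple[pd.DataFrame, int]:
    """Remove (or zero out) actions whose gap exceeds the idle cutoff.

    Removal is strict: a duration exactly equal to the cutoff is retained.
    Returns ``(filtered, n_removed)``.

    policy
        ``"drop"`` removes idle actions from both time totals and
        frequency counts (the default reading of "removed");
        ``"zero_duration"`` keeps the event for counting but attributes
        no time to it.
    """
    if not (cutoff_minutes > 0):
        raise ValueError(f"idle cutoff must be positive, got {cutoff_minutes}")
    if policy not in ("drop", "zero_duration"):
        raise ValueError(f"unknown idle policy {policy!r}")
    cutoff_s = math.inf if math.isinf(cutoff_minutes) else cutoff_minutes * 60.0
    idle = actions["duration_s"].to_numpy() > cutoff_s
    n_removed = int(idle.sum())
    if n_removed:
        logger.info("idle filter: %d of %d actions exceed %.1f min and are %s",
                    n_removed, len(actions), cutoff_minutes,
                    "removed" if policy == "drop" else "zeroed")
    if policy == "drop":
        out = actions.loc[~idle].reset_index(drop=True)
    else:
        out = actions.copy()
        out.loc[idle, "duration_s"] = 0.0
    return out, n_removed
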