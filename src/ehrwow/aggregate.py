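"""Cohort filtering and descriptive surfaces.

Everything here is expressed per physician per workday, the study's
reporting unit: a workday is a (physician, date) with at least one
retained audit-log action or at least one scheduled visit (configurable).
Per-physician averages weight workdays equally; cohort means and SDs are
taken across the per-physician averages.

Printed-table conventions: category hours to 2 decimals with integer
column percents; top-k action minutes to 1 decimal.  Totals are computed
on unrounded values and rounded last, so a rounded column may differ from
the rounded total in the final digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_schemas import CLINICAL_CATEGORIES
from .windows import ClinicWindows

__all__ = [
    "filter_cohort",
    "summarize_daily",
    "summarize_cohort",
    "category_table",
    "top_actions",
    "admin_time",
    "high_users",
    "CohortSummary",
    "DAILY_COLUMNS",
]

DEFAULT_HIGH_USER_THRESHOLD_HOURS = 1.5
DEFAULT_ADMIN_FRACTION = 0.11

#: Clinical categories used in the top-k frequency table (the two
#: session-management categories are excluded there).
TOP_K_CATEGORIES = ("review", "documentation", "inbox", "orders")


def filter_cohort(
    roster: pd.DataFrame,
    visits: pd.DataFrame,
    events: pd.DataFrame | None = None,
) -> tuple[list[str], dict[str, int]]:
    """Apply the cohort eligibility rules; returns (eligible_ids, exclusion tally).

    Excluded, in order of precedence: contingent employment status, zero
    clinical FTE, and physicians with no scheduled visits in the study
    period.  ``events`` is accepted for signature symmetry but eligibility
    never depends on log volume.
    """
    tally = {"contingent": 0, "zero_cfte": 0, "no_visits": 0}
    with_visits = set(visits["physician_id"].astype(str)) if len(visits) else set()
    eligible: list[str] = []
    for row in roster.itertuples(index=False):
        pid = str(row.physician_id)
        if row.employment_status == "contingent":
            tally["contingent"] += 1
        elif row.cfte == 0:
            tally["zero_cfte"] += 1
        elif pid not in with_visits:
            tally["no_visits"] += 1
        else:
            eligible.append(pid)
    return eligible, tally


def _daily_column_names() -> list[str]:
    cols = ["physician_id", "date", "workday_flag", "hours_during", "hours_outside"]
    for cat in CLINICAL_CATEGORIES:
        cols += [
            f"hours_during_{cat}",
            f"hours_outside_{cat}",
            f"count_during_{cat}",
            f"count_outside_{cat}",
        ]
    return cols


DAILY_COLUMNS = tuple(_daily_column_names())


def summarize_daily(
    segmented: pd.DataFrame,
    windows: ClinicWindows,
    workday_rule: str = "either",
) -> pd.DataFrame:
    """Collapse segmented, categorized actions to one row per physician-day.

    A row exists for every (physician, date) with at least one retained
    action or at least one scheduled visit; days with visits but no
    retained actions appear with zero hours.  ``workday_flag`` follows
    ``workday_rule``: "events" (≥1 retained action), "visits" (≥1
    scheduled visit) or "either" (default).
    """
    if workday_rule not in ("events", "visits", "either"):
        raise ValueError(f"unknown workday rule {workday_rule!r}")
    cats = list(CLINICAL_CATEGORIES)
    if len(segmented) and (segmented["clinical_category"] == "uncategorized").any():
        cats = cats + ["uncategorized"]

    if len(segmented):
        df = segmented.copy()
        df["physician_id"] = df["user_id"].astype(str)
        df["date"] = df["timestamp"].dt.date
        df["_count_during"] = (df["primary_segment"] == "during").astype(int)
        df["_count_outside"] = 1 - df["_count_during"]
        g = df.groupby(["physician_id", "date", "clinical_category"], sort=True, observed=True).agg(
            hours_during=("during_s", lambda s: s.sum() / 3600.0),
            hours_outside=("outside_s", lambda s: s.sum() / 3600.0),
            count_during=("_count_during", "sum"),
            count_outside=("_count_outside", "sum"),
        )
        wide = g.unstack("clinical_category", fill_value=0)
        wide.columns = [f"{stat}_{cat}" for stat, cat in wide.columns]
        wide = wide.reset_index()
    else:
        wide = pd.DataFrame(columns=["physician_id", "date"])
    for cat in cats:
        for stat in ("hours_during", "hours_outside", "count_during", "count_outside"):
            col = f"{stat}_{cat}"
            if col not in wide.columns:
                wide[col] = 0.0 if stat.startswith("hours") else 0

    # days with visits but no retained events
    visit_days = (
        windows.per_day[["physician_id", "date"]].drop_duplicates()
        if len(windows.per_day)
        else pd.DataFrame(columns=["physician_id", "date"])
    )
    event_days = wide[["physician_id", "date"]]
    merged = wide.merge(visit_days.assign(_has_visit=True), on=["physician_id", "date"], how="outer")
    merged["_has_visit"] = merged["_has_visit"].astype("boolean").fillna(False).astype(bool)
    merged["_has_events"] = merged["physician_id"].isin(event_days["physician_id"]) & merged.set_index(
        ["physician_id", "date"]
    ).index.isin(event_days.set_index(["physician_id", "date"]).index)
    num_cols = [c for c in merged.columns if c.startswith(("hours_", "count_"))]
    merged[num_cols] = merged[num_cols].fillna(0)
    for c in merged.columns:
        if c.startswith("count_"):
            merged[c] = merged[c].astype(int)

    merged["hours_during"] = merged[[f"hours_during_{c}" for c in cats]].sum(axis=1)
    merged["hours_outside"] = merged[[f"hours_outside_{c}" for c in cats]].sum(axis=1)
    if workday_rule == "either":
        merged["workday_flag"] = True
    elif workday_rule == "events":
        merged["workday_flag"] = merged["_has_events"]
    else:
        merged["workday_flag"] = merged["_has_visit"]

    cols = ["physician_id", "date", "workday_flag", "hours_during", "hours_outside"]
    for cat in cats:
        cols += [f"hours_during_{cat}", f"hours_outside_{cat}", f"count_during_{cat}", f"count_outside_{cat}"]
    out = merged[cols].sort_values(["physician_id", "date"]).reset_index(drop=True)
    return out


@dataclass
class CohortSummary:
    """Cohort-level reporting surface (descriptive tables)."""

    n_physicians: int
    n_workdays: int
    mean_hours_during: float
    sd_hours_during: float
    mean_hours_outside: float
    sd_hours_outside: float
    per_physician: pd.DataFrame
    category_table: pd.DataFrame
    top_actions: pd.DataFrame | None = None
    admin_hours_per_workday: float | None = None
    high_user_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """One-row tidy frame of the scalar cohort statistics."""
        return pd.DataFrame(
            [
                dict(
                    n_physicians=self.n_physicians,
                    n_workdays=self.n_workdays,
                    mean_hours_during=self.mean_hours_during,
                    sd_hours_during=self.sd_hours_during,
                    mean_hours_outside=self.mean_hours_outside,
                    sd_hours_outside=self.sd_hours_outside,
                    admin_hours_per_workday=self.admin_hours_per_workday,
                    n_high_users=len(self.high_user_ids),
                )
            ]
        )


def _per_physician_means(daily: pd.DataFrame) -> pd.DataFrame:
    d = daily[daily["workday_flag"]]
    hour_cols = [c for c in d.columns if c.startswith("hours_")]
    g = d.groupby("physician_id")[hour_cols].mean()
    g["n_workdays"] = d.groupby("physician_id").size()
    return g.reset_index()


def category_table(daily: pd.DataFrame) -> pd.DataFrame:
    """Mean hours per physician per workday by category × segment, with percents.

    Rows: the clinical categories (plus ``uncategorized`` if present) and
    a Total row.  Hours are cohort means of per-physician per-workday
    means; percents are each category's share of the segment column
    (integer-rounded; computed before rounding the hours).
    """
    per_phys = _per_physician_means(daily)
    cats = [c for c in CLINICAL_CATEGORIES] + (
        ["uncategorized"] if "hours_during_uncategorized" in daily.columns else []
    )
    rows = []
    for cat in cats:
        rows.append(
            dict(
                category=cat,
                hours_during=per_phys[f"hours_during_{cat}"].mean(),
                hours_outside=per_phys[f"hours_outside_{cat}"].mean(),
            )
        )
    tab = pd.DataFrame(rows)
    tab["hours_total"] = tab["hours_during"] + tab["hours_outside"]
    totals = tab[["hours_during", "hours_outside", "hours_total"]].sum()
    for col in ("during", "outside", "total"):
        denom = totals[f"hours_{col}"]
        share = np.where(denom > 0, tab[f"hours_{col}"] / max(denom, 1e-300), 0.0)
        tab[f"pct_{col}"] = np.round(100.0 * share).astype(int)
    total_row = dict(
        category="total",
        hours_during=totals["hours_during"],
        hours_outside=totals["hours_outside"],
        hours_total=totals["hours_total"],
        pct_during=100 if totals["hours_during"] > 0 else 0,
        pct_outside=100 if totals["hours_outside"] > 0 else 0,
        pct_total=100 if totals["hours_total"] > 0 else 0,
    )
    tab = pd.concat([tab, pd.DataFrame([total_row])], ignore_index=True)
    for col in ("hours_during", "hours_outside", "hours_total"):
        tab[col] = np.round(tab[col], 2)
    return tab[["category", "hours_during", "pct_during", "hours_outside", "pct_outside", "hours_total", "pct_total"]]


def top_actions(
    segmented: pd.DataFrame,
    n_workdays: int,
    k: int = 3,
    segment: str = "outside",
    categories: tuple[str, ...] = TOP_K_CATEGORIES,
) -> pd.DataFrame:
    """Top-k most frequent actions per clinical category in one segment.

    Frequency is the count of actions whose primary segment matches,
    per physician-workday; minutes are the time attributed to that
    segment per physician-workday (1 decimal).  Ties in frequency break
    by larger minutes, then lexicographic action code.  A grand-total row
    (category="total") sums the selected rows before rounding.
    """
    if n_workdays <= 0:
        raise ValueError("n_workdays must be positive")
    time_col = "outside_s" if segment == "outside" else "during_s"
    df = segmented[segmented["clinical_category"].isin(categories)]
    g = (
        df.assign(_hit=(df["primary_segment"] == segment).astype(int))
        .groupby(["clinical_category", "action_code"], observed=True)
        .agg(n=("_hit", "sum"), seconds=(time_col, "sum"))
        .reset_index()
    )
    g["freq_per_workday"] = g["n"] / n_workdays
    g["minutes_per_workday"] = g["seconds"] / 60.0 / n_workdays
    g = g.sort_values(
        ["clinical_category", "freq_per_workday", "minutes_per_workday", "action_code"],
        ascending=[True, False, False, True],
    )
    picked = g.groupby("clinical_category", observed=True).head(k).copy()
    picked["clinical_category"] = pd.Categorical(picked["clinical_category"], categories=categories, ordered=True)
    picked = picked.sort_values(["clinical_category", "freq_per_workday"], ascending=[True, False])
    total = dict(
        clinical_category="total",
        action_code="",
        freq_per_workday=picked["freq_per_workday"].sum(),
        minutes_per_workday=picked["minutes_per_workday"].sum(),
    )
    out = pd.concat(
        [picked[["clinical_category", "action_code", "freq_per_workday", "minutes_per_workday"]].astype(
            {"clinical_category": str}
        ), pd.DataFrame([total])],
        ignore_index=True,
    )
    out["frequency"] = np.round(out["freq_per_workday"]).astype(int)
    out["minutes"] = np.round(out["minutes_per_workday"], 1)
    return out


def admin_time(
    planned_clinic_hours: float,
    admin_fraction: float = DEFAULT_ADMIN_FRACTION,
    n_workdays: int = 1,
) -> float:
    """Administrative hours per workday: a fixed fraction of nominal clinical hours."""
    if n_workdays <= 0:
        raise ValueError("n_workdays must be positive")
    return admin_fraction * planned_clinic_hours / n_workdays


def summarize_cohort(
    daily: pd.DataFrame,
    segmented: pd.DataFrame | None = None,
    k_top: int = 3,
    high_user_threshold: float = DEFAULT_HIGH_USER_THRESHOLD_HOURS,
    planned_clinic_hours: float | None = None,
    admin_fraction: float = DEFAULT_ADMIN_FRACTION,
) -> CohortSummary:
    """Build the full cohort summary surface from daily summaries.

    ``segmented`` (action-level data) is needed for the top-k action
    table; without it that table is omitted.  Cohort means/SDs are taken
    across per-physician per-workday means.
    """
    d = daily[daily["workday_flag"]]
    per_phys = _per_physician_means(daily)
    n_phys = len(per_phys)
    n_workdays = int(len(d))
    if n_phys == 0:
        return CohortSummary(
            n_physicians=0, n_workdays=0,
            mean_hours_during=float("nan"), sd_hours_during=float("nan"),
            mean_hours_outside=float("nan"), sd_hours_outside=float("nan"),
            per_physician=per_phys, category_table=pd.DataFrame(),
        )
    tab = category_table(daily)
    top = top_actions(segmented, n_workdays, k=k_top) if segmented is not None and len(segmented) else None
    admin = (
        admin_time(planned_clinic_hours, admin_fraction, n_workdays)
        if planned_clinic_hours is not None
        else None
    )
    high = per_phys.loc[per_phys["hours_outside"] > high_user_threshold, "physician_id"].tolist()
    return CohortSummary(
        n_physicians=n_phys,
        n_workdays=n_workdays,
        mean_hours_during=float(per_phys["hours_during"].mean()),
        sd_hours_during=float(per_phys["hours_during"].std(ddof=1)) if n_phys > 1 else 0.0,
        mean_hours_outside=float(per_phys["hours_outside"].mean()),
        sd_hours_outside=float(per_phys["hours_outside"].std(ddof=1)) if n_phys > 1 else 0.0,
        per_physician=per_phys,
        category_table=tab,
        top_actions=top,
        admin_hours_per_workday=admin,
        high_user_ids=sorted(high),
    )


def high_users(
    daily: pd.DataFrame,
    threshold: float = DEFAULT_HIGH_USER_THRESHOLD_HOURS,
    segmented: pd.DataFrame | None = None,
    k_top: int = 3,
) -> tuple[list[str], CohortSummary]:
    """Physicians whose mean outside-hours per workday strictly exceeds ``threshold``.

    Returns their ids and the cohort summary restricted to them (empty
    subgroup → empty summary, no error).
    """
    per_phys = _per_physician_means(daily)
    ids = sorted(per_phys.loc[per_phys["hours_outside"] > threshold, "physician_id"].tolist())
    sub_daily = daily[daily["physician_id"].isin(ids)]
    sub_seg = None
    if segmented is not None and len(segmented):
        sub_seg = segmented[segmented["user_id"].astype(str).isin(ids)]
    summary = summarize_cohort(sub_daily, segmented=sub_seg, k_top=k_top, high_user_threshold=threshold)
    return ids, summary
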