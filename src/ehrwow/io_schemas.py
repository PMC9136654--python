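"""Readers, writers and validation for the four input CSV schemas.

All inputs are comma-separated UTF-8 with a header row (RFC-4180 quoting).
Timestamps carry no zone offset and are interpreted on a single local
clinic clock; the study design (one site, one month) makes DST handling
unnecessary.

In-memory containers are pandas DataFrames with fixed column names;
validation failures raise :class:`SchemaError` carrying 1-based data-row
line numbers so a malformed export can be fixed at the source.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "CLINICAL_CATEGORIES",
    "CONCEPTUAL_CATEGORIES",
    "CLINICAL_TO_CONCEPTUAL",
    "read_access_log",
    "read_visits",
    "read_roster",
    "read_action_map",
    "write_access_log",
    "write_visits",
    "write_roster",
    "write_action_map",
]


class SchemaError(ValueError):
    """An input file violates its schema contract."""


#: The six-way clinical taxonomy of audit-log actions.
CLINICAL_CATEGORIES = ("review", "documentation", "inbox", "orders", "login", "logout")

#: The four-way conceptual taxonomy (data review / entry / transmission / other).
CONCEPTUAL_CATEGORIES = ("data_review", "data_entry", "data_transmission", "other")

#: Fixed projection of clinical onto conceptual categories.  Reviewing is
#: data review; documentation and order entry both record information and
#: are data entry; inbox work transmits information; session management
#: (log-in/logout) is non-clinical "other".
CLINICAL_TO_CONCEPTUAL = {
    "review": "data_review",
    "documentation": "data_entry",
    "orders": "data_entry",
    "inbox": "data_transmission",
    "login": "other",
    "logout": "other",
}


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}; found {list(df.columns)}")


def _parse_timestamps(raw: pd.Series, what: str, column: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
        sample = raw[bad].iloc[0]
        raise SchemaError(
            f"{what}: unparsable {column} at data row(s) {lines[:10]}"
            f"{'...' if len(lines) > 10 else ''} (first offending value: {sample!r})"
        )
    if raw.isna().any():
        lines = (np.flatnonzero(raw.isna().to_numpy()) + 1).tolist()
        raise SchemaError(f"{what}: empty {column} at data row(s) {lines[:10]}")
    return parsed


def read_access_log(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read an audit-log export: one row per time-stamped user action.

    Returns a frame with columns ``user_id``, ``timestamp`` (datetime64),
    ``action_code``, ``source`` (may be all-NA) sorted by
    ``(user_id, timestamp)`` with file order breaking ties (stable sort);
    the original 0-based file position is kept in ``file_order``.
    """
    df = pd.read_csv(path, dtype={"user_id": str, "action_code": str, "source": str})
    _require_columns(df, ("user_id", "timestamp", "action_code"), "access log")
    if "source" not in df.columns:
        df["source"] = pd.NA
    df["timestamp"] = _parse_timestamps(df["timestamp"], "access log", "timestamp")
    empty = df["action_code"].isna() | (df["action_code"].astype(str).str.len() == 0)
    if empty.any():
        lines = (np.flatnonzero(empty.to_numpy()) + 1).tolist()
        raise SchemaError(f"access log: empty action_code at data row(s) {lines[:10]}")
    df["file_order"] = np.arange(len(df))
    df = df.sort_values(["user_id", "timestamp", "file_order"], kind="stable")
    return df.reset_index(drop=True)[["user_id", "timestamp", "action_code", "source", "file_order"]]


def read_visits(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read scheduled patient visits: ``physician_id``, ``start``, ``end``.

    Each visit must satisfy ``start < end`` and last at most 24 hours.
    """
    df = pd.read_csv(path, dtype={"physician_id": str})
    _require_columns(df, ("physician_id", "start", "end"), "visits")
    df["start"] = _parse_timestamps(df["start"], "visits", "start")
    df["end"] = _parse_timestamps(df["end"], "visits", "end")
    bad = df["end"] <= df["start"]
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
        raise SchemaError(f"visits: end <= start at data row(s) {lines[:10]}")
    too_long = (df["end"] - df["start"]) > pd.Timedelta(hours=24)
    if too_long.any():
        lines = (np.flatnonzero(too_long.to_numpy()) + 1).tolist()
        raise SchemaError(f"visits: duration exceeds 24 h at data row(s) {lines[:10]}")
    return df.reset_index(drop=True)[["physician_id", "start", "end"]]


_ROSTER_COLUMNS = ("physician_id", "age", "sex", "service_years", "fte", "cfte", "employment_status")


def read_roster(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read the physician roster with demographics and workload fractions.

    Enforces ``0 <= cfte <= fte <= 1``, positive age, non-negative length
    of service, ``sex`` in {male, female} and ``employment_status`` in
    {regular, contingent}.
    """
    df = pd.read_csv(path, dtype={"physician_id": str, "sex": str, "employment_status": str})
    _require_columns(df, _ROSTER_COLUMNS, "roster")

    def _bad_rows(mask: pd.Series, message: str) -> None:
        if mask.any():
            lines = (np.flatnonzero(mask.to_numpy()) + 1).tolist()
            raise SchemaError(f"roster: {message} at data row(s) {lines[:10]}")

    _bad_rows(~df["sex"].isin(["male", "female"]), "sex must be 'male' or 'female'")
    _bad_rows(
        ~df["employment_status"].isin(["regular", "contingent"]),
        "employment_status must be 'regular' or 'contingent'",
    )
    _bad_rows(~(df["age"] > 0), "age must be positive")
    _bad_rows(~(df["service_years"] >= 0), "service_years must be non-negative")
    _bad_rows(~((df["fte"] >= 0) & (df["fte"] <= 1)), "fte must lie in [0, 1]")
    _bad_rows(~((df["cfte"] >= 0) & (df["cfte"] <= df["fte"])), "cfte must lie in [0, fte]")
    _bad_rows(df["physician_id"].duplicated(), "duplicate physician_id")
    return df.reset_index(drop=True)[list(_ROSTER_COLUMNS)]


def read_action_map(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read the action-code → category map.

    Columns: ``action_code``, ``clinical_category`` (six-way),
    ``conceptual_category`` (four-way).  Duplicate codes with conflicting
    categories are rejected; exact duplicate rows are collapsed.  The
    conceptual column must follow the fixed clinical→conceptual projection.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("action_code", "clinical_category", "conceptual_category"), "action map")
    bad_clin = ~df["clinical_category"].isin(CLINICAL_CATEGORIES)
    if bad_clin.any():
        lines = (np.flatnonzero(bad_clin.to_numpy()) + 1).tolist()
        raise SchemaError(
            f"action map: unknown clinical_category at data row(s) {lines[:10]} "
            f"(allowed: {list(CLINICAL_CATEGORIES)})"
        )
    expected = df["clinical_category"].map(CLINICAL_TO_CONCEPTUAL)
    mismatch = df["conceptual_category"] != expected
    if mismatch.any():
        lines = (np.flatnonzero(mismatch.to_numpy()) + 1).tolist()
        raise SchemaError(
            f"action map: conceptual_category inconsistent with the fixed "
            f"clinical→conceptual projection at data row(s) {lines[:10]}"
        )
    df = df.drop_duplicates()
    conflicts = df["action_code"].duplicated(keep=False)
    if conflicts.any():
        codes = sorted(df.loc[conflicts, "action_code"].unique())
        raise SchemaError(f"action map: conflicting categories for action_code(s) {codes[:10]}")
    return df.reset_index(drop=True)[["action_code", "clinical_category", "conceptual_category"]]


# -- writers: exact inverses of the readers on the data model ---------------

def _write(df: pd.DataFrame, path: str | Path | io.IOBase, datetime_cols: tuple[str, ...]) -> None:
    out = df.copy()
    for col in datetime_cols:
        out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_access_log(df: pd.DataFrame, path: str | Path | io.IOBase) -> None:
    cols = [c for c in ("user_id", "timestamp", "action_code", "source") if c in df.columns]
    _write(df[cols], path, ("timestamp",))


def write_visits(df: pd.DataFrame, path: str | Path | io.IOBase) -> None:
    _write(df[["physician_id", "start", "end"]], path, ("start", "end"))


def write_roster(df: pd.DataFrame, path: str | Path | io.IOBase) -> None:
    df[list(_ROSTER_COLUMNS)].to_csv(path, index=False)


def write_action_map(df: pd.DataFrame, path: str | Path | io.IOBase) -> None:
    df[["action_code", "clinical_category", "conceptual_category"]].to_csv(path, index=False)
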