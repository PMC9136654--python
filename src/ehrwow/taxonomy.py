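"""Action categorization: the six-way clinical and four-way conceptual taxonomies.

Every audit-log action code belongs to one of six clinical categories —
reviewing data and reports, creating/authenticating documentation,
inbox/communication tasks, entering/authenticating orders, log-in, logout —
and the clinical label fixes the conceptual one (data review / data entry /
data transmission / other).  The projection is not overridable per code:
review → data_review; documentation and orders → data_entry;
inbox → data_transmission; login and logout → other.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_schemas import CLINICAL_CATEGORIES, CLINICAL_TO_CONCEPTUAL

__all__ = ["UnmappedActionError", "categorize", "vocabulary_composition"]


class UnmappedActionError(KeyError):
    """An action code has no entry in the category map (strict policy)."""


def categorize(
    actions: pd.DataFrame,
    action_map: pd.DataFrame,
    unmapped_policy: str = "strict",
) -> pd.DataFrame:
    """Attach ``clinical_category`` and ``conceptual_category`` to actions.

    Categorization is a pure function of the action code and the map.
    Under ``unmapped_policy="strict"`` (default) an unknown code raises
    :class:`UnmappedActionError` naming the code; ``"uncategorized"``
    instead routes unknown codes to an explicit ``uncategorized`` bucket
    reported separately in downstream tables.
    """
    if unmapped_policy not in ("strict", "uncategorized"):
        raise ValueError(f"unknown unmapped policy {unmapped_policy!r}")
    clin = actions["action_code"].map(
        pd.Series(action_map["clinical_category"].to_numpy(), index=action_map["action_code"])
    )
    missing = clin.isna()
    if missing.any():
        if unmapped_policy == "strict":
            codes = sorted(actions.loc[missing, "action_code"].unique())
            raise UnmappedActionError(f"unmapped action code(s): {codes[:10]}")
        clin = clin.fillna("uncategorized")
    out = actions.copy()
    out["clinical_category"] = clin
    out["conceptual_category"] = clin.map(CLINICAL_TO_CONCEPTUAL).fillna("uncategorized")
    return out


def vocabulary_composition(action_map: pd.DataFrame) -> pd.DataFrame:
    """Composition of the action vocabulary by clinical category.

    Returns (clinical_category, n_codes, percent_of_codes) with percents
    computed as ``100 * n_codes / total`` rounded to 1 decimal, so the
    column sums to 100 within rounding.
    """
    if len(action_map) == 0:
        raise ValueError("action map is empty")
    counts = (
        action_map.drop_duplicates("action_code")
        .groupby("clinical_category", sort=False)["action_code"]
        .size()
        .reindex(CLINICAL_CATEGORIES, fill_value=0)
    )
    total = int(counts.sum())
    out = counts.rename("n_codes").reset_index().rename(columns={"index": "clinical_category"})
    out["percent_of_codes"] = np.round(100.0 * out["n_codes"] / total, 1)
    return out
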