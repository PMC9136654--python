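"""End-to-end pipeline orchestration.

One call runs the whole analysis: cohort filtering, access-time
estimation, idle removal, clinic-window construction, during/outside
segmentation, categorization, the daily and cohort summaries, and the
crossed random-effects models — returning every intermediate surface and
(optionally) writing the output CSV/JSON files plus a run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate, mixedmodel, sessionize, taxonomy, windows as windows_mod
from .aggregate import CohortSummary
from .config import PipelineConfig
from .io_schemas import read_access_log, read_action_map, read_roster, read_visits
from .mixedmodel import MixedModelResult, ModelSpec

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_files", "write_outputs"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    eligible_ids: list[str]
    exclusions: dict[str, int]
    n_events_raw: int
    n_idle_removed: int
    segmented: pd.DataFrame
    clinic_windows: windows_mod.ClinicWindows
    daily: pd.DataFrame
    cohort: CohortSummary
    models: list[MixedModelResult]
    diagnostics: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return dict(
            config=self.config.to_dict(),
            config_digest=self.config.digest(),
            n_events_raw=self.n_events_raw,
            n_events_retained=int(len(self.segmented)),
            n_idle_removed=self.n_idle_removed,
            exclusions=self.exclusions,
            n_eligible=len(self.eligible_ids),
            n_workdays=self.cohort.n_workdays,
            n_models=len(self.models),
            seed=self.config.seed,
        )


def run_pipeline(
    events: pd.DataFrame,
    visits: pd.DataFrame,
    roster: pd.DataFrame,
    action_map: pd.DataFrame,
    config: PipelineConfig | None = None,
    fit_models: bool = True,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs (reader-contract frames)."""
    cfg = config or PipelineConfig()

    eligible, exclusions = aggregate.filter_cohort(roster, visits, events)
    logger.info("cohort: %d eligible, exclusions %s", len(eligible), exclusions)
    events_elig = events[events["user_id"].astype(str).isin(eligible)]
    visits_elig = visits[visits["physician_id"].astype(str).isin(eligible)]
    roster_elig = roster[roster["physician_id"].astype(str).isin(eligible)]

    timed = sessionize.estimate_access_time(events_elig.reset_index(drop=True), cfg.idle_cutoff_minutes)
    n_raw = len(timed)
    retained, n_removed = sessionize.filter_idle(timed, cfg.idle_cutoff_minutes, cfg.idle_policy)

    wins = windows_mod.build_windows(visits_elig, cfg.margin_minutes)
    segmented = windows_mod.segment_actions(retained, wins, cfg.straddle_policy)
    segmented = taxonomy.categorize(segmented, action_map, cfg.unmapped_policy)

    daily = aggregate.summarize_daily(segmented, wins, cfg.workday_rule)
    planned_hours = float((visits_elig["end"] - visits_elig["start"]).dt.total_seconds().sum() / 3600.0)
    cohort = aggregate.summarize_cohort(
        daily,
        segmented=segmented,
        k_top=cfg.k_top,
        high_user_threshold=cfg.high_user_threshold_hours,
        planned_clinic_hours=planned_hours,
        admin_fraction=cfg.admin_fraction,
    )

    models: list[MixedModelResult] = []
    diagnostics: dict = {}
    if fit_models:
        for aggregation in cfg.aggregations:
            for outcome in cfg.outcomes:
                spec = ModelSpec(outcome=outcome, aggregation=aggregation, transform=cfg.transform)
                res = mixedmodel.fit_mixed(daily, roster_elig, spec)
                models.append(res)
        # residual-normality diagnostics on the daily outcome series
        for outcome in cfg.outcomes:
            col = {"during": "hours_during", "outside": "hours_outside"}.get(outcome)
            y = (
                daily[col]
                if col
                else daily["hours_during"] + daily["hours_outside"]
            )
            diagnostics[outcome] = mixedmodel.normality_check(
                np.asarray(y, dtype=float) - float(np.mean(y)), cfg.skew_threshold
            )

    return PipelineResult(
        config=cfg,
        eligible_ids=eligible,
        exclusions=exclusions,
        n_events_raw=n_raw,
        n_idle_removed=n_removed,
        segmented=segmented,
        clinic_windows=wins,
        daily=daily,
        cohort=cohort,
        models=models,
        diagnostics=diagnostics,
    )


def run_pipeline_files(
    log_path: str | Path,
    visits_path: str | Path,
    roster_path: str | Path,
    map_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    fit_models: bool = True,
) -> PipelineResult:
    """File-based entry point: read the four inputs, run, optionally write outputs."""
    events = read_access_log(log_path)
    visits = read_visits(visits_path)
    roster = read_roster(roster_path)
    action_map = read_action_map(map_path)
    result = run_pipeline(events, visits, roster, action_map, config=config, fit_models=fit_models)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the tidy output tables, model JSON, and run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["daily_summary"] = out / "daily_summary.csv"
    result.daily.to_csv(paths["daily_summary"], index=False)

    paths["cohort_summary"] = out / "cohort_summary.csv"
    result.cohort.to_frame().to_csv(paths["cohort_summary"], index=False)

    paths["category_table"] = out / "category_table.csv"
    result.cohort.category_table.to_csv(paths["category_table"], index=False)

    paths["top_actions"] = out / "top_actions.csv"
    top = result.cohort.top_actions
    (top if top is not None else pd.DataFrame()).to_csv(paths["top_actions"], index=False)

    paths["model_results"] = out / "model_results.json"
    with open(paths["model_results"], "w") as fh:
        json.dump(
            dict(models=[m.to_dict() for m in result.models], diagnostics=result.diagnostics),
            fh,
            indent=1,
        )

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest(), fh, indent=1)
    return paths
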