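"""Seedable generator of a full synthetic study cohort.

The generator emulates one month of audit-log data from a primary-care
group: a roster of 62 physicians (56 eligible; 4 contingent, 1 with zero
clinical FTE, 1 who sees no patients), half-day visit sessions of 20-min
appointments on attended weekdays, a 290-code action vocabulary split
161/64/34/19/12 across the six clinical categories, and per-physician-day
EHR time budgets with cohort structure matching the reference study
population: time during clinic hours averaging 4.4 h (between-physician
SD 2.0) and outside clinic hours 0.8 h (SD 0.8, floored at zero so a
subset of physicians never works outside clinic hours).

Event streams are built burst-wise: each physician-day's during-budget is
spent inside that day's clinic windows as bursts of events whose
inter-event gaps (log-normal, renormalized to the budget, all below the
idle cutoff) sum exactly to the budget; bursts are separated by idle gaps
longer than the cutoff, and the outside-budget is placed in an evening
block (plus occasional weekend activity).  Ground truth — the realized
per-physician-day budgets actually encoded in the event stream — is
emitted in a sidecar record, never in the observed CSVs, so pipeline
recovery can be checked exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_schemas
from .io_schemas import CLINICAL_CATEGORIES, CLINICAL_TO_CONCEPTUAL

__all__ = ["GeneratorConfig", "SimulatedStudy", "simulate_cohort", "simulate_model_data", "make_action_map"]

logger = logging.getLogger(__name__)

_DAY_S = 86400.0


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults encode the reference population: 56 eligible physicians over
    one calendar month of weekdays, ~4.4/0.8 h during/outside clinic per
    workday, a 290-code vocabulary, and a mean inter-event gap sized so a
    month yields ~1.5 M events.
    """

    n_physicians: int = 56
    n_contingent: int = 4
    n_zero_cfte: int = 1
    n_no_visits: int = 1
    period_start: str = "2019-09-01"
    period_days: int = 30

    during_mean_h: float = 4.4
    during_sd_h: float = 2.0            # between physicians
    during_day_sd_h: float = 1.5        # day-to-day within physician
    during_range_h: tuple[float, float] = (0.7, 8.2)
    outside_mean_h: float = 0.8
    outside_sd_h: float = 0.8           # between physicians; floored at 0
    outside_day_sd_h: float = 0.5

    # per-segment category time shares (review, documentation, inbox,
    # orders, login, logout)
    category_shares_during: tuple[float, ...] = (3.13, 0.28, 0.52, 0.12, 0.03, 0.28)
    category_shares_outside: tuple[float, ...] = (0.59, 0.05, 0.08, 0.01, 0.01, 0.02)

    vocab_size: int = 290
    category_code_counts: tuple[int, ...] = (161, 64, 34, 19, 6, 6)

    visit_minutes: float = 20.0
    morning_session: tuple[str, str] = ("08:00", "11:00")
    afternoon_session: tuple[str, str] = ("13:00", "16:00")
    attendance_rate: float = 0.9
    weekend_rate: float = 0.05
    evening_start: str = "18:00"
    evening_end: str = "23:30"

    age_mean: float = 45.6
    age_sd: float = 9.9
    age_range: tuple[float, float] = (30.0, 69.0)
    service_mean: float = 10.1
    service_sd: float = 7.6
    fte_mean: float = 0.8
    fte_sd: float = 0.2
    cfte_mean: float = 0.5
    cfte_sd: float = 0.2
    p_female: float = 44 / 56

    mean_gap_s: float = 12.9
    gap_sigma: float = 1.0              # log-normal shape of inter-event gaps
    idle_cutoff_minutes: float = 15.0
    idle_gap_minutes: tuple[float, float] = (16.0, 25.0)
    max_bursts_per_window: int = 2

    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.category_code_counts) - self.vocab_size) > 0:
            raise ValueError("category_code_counts must sum to vocab_size")
        for name in ("during_sd_h", "outside_sd_h", "during_day_sd_h", "outside_day_sd_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.attendance_rate <= 1):
            raise ValueError("attendance_rate must lie in (0, 1]")


@dataclass
class SimulatedStudy:
    """The four observed inputs plus the ground-truth sidecar."""

    roster: pd.DataFrame
    visits: pd.DataFrame
    action_map: pd.DataFrame
    events: pd.DataFrame
    ground_truth: dict
    n_truncated_budgets: int = 0

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "roster": out / "roster.csv",
            "visits": out / "visits.csv",
            "action_map": out / "action_map.csv",
            "access_log": out / "access_log.csv",
            "ground_truth": out / "ground_truth.json",
        }
        io_schemas.write_roster(self.roster, paths["roster"])
        io_schemas.write_visits(self.visits, paths["visits"])
        io_schemas.write_action_map(self.action_map, paths["action_map"])
        io_schemas.write_access_log(self.events, paths["access_log"])
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, default=str)
        return paths


def make_action_map(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Synthetic 290-code vocabulary with the configured per-category counts.

    The reference study did not publish its code-level mapping; codes here
    are synthetic labels (``review_001`` ...), with the 12 session-management
    codes split 6 log-in / 6 logout.
    """
    config = config or GeneratorConfig()
    rows = []
    for cat, n in zip(CLINICAL_CATEGORIES, config.category_code_counts):
        for i in range(n):
            code = f"{cat}_{i + 1:03d}"
            rows.append((code, cat, CLINICAL_TO_CONCEPTUAL[cat]))
    return pd.DataFrame(rows, columns=["action_code", "clinical_category", "conceptual_category"])


def _hm_to_seconds(hm: str) -> float:
    h, m = hm.split(":")
    return int(h) * 3600.0 + int(m) * 60.0


def _make_roster(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_total = config.n_physicians + config.n_contingent + config.n_zero_cfte + config.n_no_visits
    ids = [f"P{i + 1:03d}" for i in range(n_total)]
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n_total), *config.age_range)
    service = np.clip(rng.normal(config.service_mean, config.service_sd, n_total), 0.3, None)
    fte = np.clip(rng.normal(config.fte_mean, config.fte_sd, n_total), 0.5, 1.0)
    cfte = np.minimum(fte, np.clip(rng.normal(config.cfte_mean, config.cfte_sd, n_total), 0.1, 0.9))
    sex = np.where(rng.random(n_total) < config.p_female, "female", "male")
    status = np.array(["regular"] * n_total, dtype=object)
    i0 = config.n_physicians
    status[i0 : i0 + config.n_contingent] = "contingent"
    cfte[i0 + config.n_contingent : i0 + config.n_contingent + config.n_zero_cfte] = 0.0
    return pd.DataFrame(
        dict(
            physician_id=ids,
            age=np.round(age, 1),
            sex=sex,
            service_years=np.round(service, 1),
            fte=np.round(fte, 2),
            cfte=np.round(cfte, 2),
            employment_status=status,
        )
    )


def _burst_events(rng: np.random.Generator, start_s: float, budget_s: float,
                  mean_gap_s: float, sigma: float, cap_s: float) -> np.ndarray:
    """Integer-second event times encoding exactly ``budget`` seconds of gaps.

    Gaps are log-normal renormalized to the budget; any renormalized gap
    exceeding ``cap`` is split into equal sub-gaps so nothing is lost to
    the idle filter.
    """
    m = max(1, int(round(budget_s / mean_gap_s)))
    mu = np.log(mean_gap_s) - 0.5 * sigma**2
    gaps = rng.lognormal(mu, sigma, m)
    gaps *= budget_s / gaps.sum()
    over = gaps > cap_s
    if over.any():
        pieces = np.ceil(gaps[over] / cap_s).astype(int)
        split = np.repeat(gaps[over] / pieces, pieces)
        gaps = np.concatenate([gaps[~over], split])
    times = start_s + np.concatenate([[0.0], np.cumsum(gaps)])
    return np.round(times).astype(np.int64)


def _fill_block(rng, arrays, block_start, block_end, budget_s, config):
    """Place bursts totalling ``budget`` seconds of gaps in [block_start, block_end).

    Appends integer-second event-time arrays (one per burst) to
    ``arrays``; returns ``(realized_seconds, truncated)``.  Bursts are
    separated by idle gaps longer than the cutoff; the burst count is
    reduced — and as a last resort the budget clipped, with a tally — when
    the block cannot hold the budget plus separations.
    """
    if budget_s <= 0:
        return 0, False
    cap_s = config.idle_cutoff_minutes * 60.0 - 30.0
    sep_lo, sep_hi = (60.0 * g for g in config.idle_gap_minutes)
    block_len = block_end - block_start
    n_bursts = int(rng.integers(1, config.max_bursts_per_window + 1))
    while n_bursts > 1 and budget_s + (n_bursts - 1) * sep_hi + 60.0 > block_len:
        n_bursts -= 1
    capacity = block_len - (n_bursts - 1) * sep_hi - 60.0
    truncated = budget_s > capacity
    if truncated:
        budget_s = max(capacity, 60.0)
    shares = rng.dirichlet(np.ones(n_bursts) * 4.0) * budget_s
    cursor = block_start
    realized = 0
    for share in shares:
        if share < 1.0:
            continue
        t = _burst_events(rng, cursor, share, config.mean_gap_s, config.gap_sigma, cap_s)
        arrays.append(t)
        realized += int(t[-1] - t[0])
        cursor = float(t[-1]) + rng.uniform(sep_lo, sep_hi)
    return realized, truncated


def simulate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> SimulatedStudy:
    """Generate the full synthetic study (roster, visits, map, event log, truth).

    Identical ``seed`` (or ``config.seed``) gives identical output.  A
    physician-day budget that cannot fit its block is truncated with a
    warning and the truncation is tallied; ground truth records realized
    (post-truncation, integer-second) budgets, which the pipeline should
    recover exactly.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    roster = _make_roster(config, rng)
    action_map = make_action_map(config)
    codes_by_cat = {
        cat: action_map.loc[action_map["clinical_category"] == cat, "action_code"].to_numpy()
        for cat in CLINICAL_CATEGORIES
    }
    shares_during = np.asarray(config.category_shares_during, dtype=float)
    shares_during = shares_during / shares_during.sum()
    shares_outside = np.asarray(config.category_shares_outside, dtype=float)
    shares_outside = shares_outside / shares_outside.sum()

    start = pd.Timestamp(config.period_start)
    dates = [start + pd.Timedelta(days=i) for i in range(config.period_days)]
    day0 = {d: d.timestamp() for d in dates}  # midnight epoch seconds (naive = UTC clock)

    m_lo, m_hi = (_hm_to_seconds(t) for t in config.morning_session)
    a_lo, a_hi = (_hm_to_seconds(t) for t in config.afternoon_session)
    e_lo, e_hi = (_hm_to_seconds(t) for t in (config.evening_start, config.evening_end))
    visit_s = config.visit_minutes * 60.0

    eligible = roster.iloc[: config.n_physicians]
    n_elig = len(eligible)
    mu_during = np.clip(
        rng.normal(config.during_mean_h, config.during_sd_h, n_elig), *config.during_range_h
    )
    mu_outside = np.maximum(0.0, rng.normal(config.outside_mean_h, config.outside_sd_h, n_elig))

    visit_rows = []
    ev_uid: list[np.ndarray] = []
    ev_t: list[np.ndarray] = []
    ev_seg: list[int] = []  # parallel per-array segment flag (1=during target, 0=outside)
    truth_days = []
    n_truncated = 0

    for i, pid in enumerate(eligible["physician_id"]):
        for d in dates:
            base = day0[d]
            is_weekend = d.dayofweek >= 5
            if not is_weekend and rng.random() < config.attendance_rate:
                attended = True
            else:
                attended = False
            realized_during = 0.0
            realized_outside = 0.0
            day_arrays: list[np.ndarray] = []
            day_flags: list[int] = []
            if attended:
                # back-to-back 20-min visits fill both half-day sessions
                for lo, hi in ((m_lo, m_hi), (a_lo, a_hi)):
                    t = lo
                    while t + visit_s <= hi + 1:
                        visit_rows.append(
                            (pid, pd.Timestamp(base + t, unit="s"), pd.Timestamp(base + t + visit_s, unit="s"))
                        )
                        t += visit_s
                during_h = float(np.clip(rng.normal(mu_during[i], config.during_day_sd_h), 0.25, 8.5))
                # split the budget across the two clinic windows (margin 30 min each side)
                w1 = (base + m_lo - 1800.0, base + m_hi + 1800.0)
                w2 = (base + a_lo - 1800.0, base + a_hi + 1800.0)
                len1 = w1[1] - w1[0]
                len2 = w2[1] - w2[0]
                frac = len1 / (len1 + len2) * rng.uniform(0.9, 1.1)
                frac = min(max(frac, 0.4), 0.6)
                for (lo_w, hi_w), b in ((w1, during_h * 3600.0 * frac), (w2, during_h * 3600.0 * (1 - frac))):
                    arrays: list[np.ndarray] = []
                    r, trunc = _fill_block(rng, arrays, lo_w, hi_w, b, config)
                    n_truncated += int(trunc)
                    realized_during += r
                    day_arrays.extend(arrays)
                    day_flags.extend([1] * len(arrays))
            if mu_outside[i] > 0:
                if attended:
                    outside_h = max(0.0, float(rng.normal(mu_outside[i], config.outside_day_sd_h)))
                elif is_weekend and rng.random() < config.weekend_rate:
                    outside_h = max(0.1, float(rng.normal(mu_outside[i], config.outside_day_sd_h)))
                else:
                    outside_h = 0.0
                if outside_h > 0:
                    arrays = []
                    r, trunc = _fill_block(rng, arrays, base + e_lo, base + e_hi, outside_h * 3600.0, config)
                    n_truncated += int(trunc)
                    realized_outside += r
                    day_arrays.extend(arrays)
                    day_flags.extend([0] * len(arrays))
            if day_arrays:
                for arr, flag in zip(day_arrays, day_flags):
                    ev_uid.append(np.repeat(pid, len(arr)))
                    ev_t.append(arr)
                    ev_seg.append(flag)
            if attended or day_arrays:
                truth_days.append(
                    dict(
                        physician_id=pid,
                        date=str(d.date()),
                        attended=attended,
                        true_during_h=realized_during / 3600.0,
                        true_outside_h=realized_outside / 3600.0,
                    )
                )

    # a few visits for the contingent / zero-cFTE physicians (they are
    # excluded by status or cFTE, not for lack of visits)
    i0 = config.n_physicians
    for pid in roster["physician_id"].iloc[i0 : i0 + config.n_contingent + config.n_zero_cfte]:
        for d in dates[:3]:
            if d.dayofweek < 5:
                base = day0[d]
                visit_rows.append(
                    (pid, pd.Timestamp(base + m_lo, unit="s"), pd.Timestamp(base + m_lo + visit_s, unit="s"))
                )

    visits = pd.DataFrame(visit_rows, columns=["physician_id", "start", "end"])

    # assemble the event frame; draw categories per event by segment-specific
    # time shares, then codes uniformly within category
    if ev_t:
        all_t = np.concatenate(ev_t)
        all_uid = np.concatenate(ev_uid)
        all_seg = np.concatenate([np.full(len(t), s, dtype=np.int8) for t, s in zip(ev_t, ev_seg)])
        n = len(all_t)
        cat_idx = np.empty(n, dtype=np.int64)
        for seg_val, shares in ((1, shares_during), (0, shares_outside)):
            mask = all_seg == seg_val
            cat_idx[mask] = rng.choice(len(CLINICAL_CATEGORIES), size=int(mask.sum()), p=shares)
        codes = np.empty(n, dtype=object)
        for ci, cat in enumerate(CLINICAL_CATEGORIES):
            mask = cat_idx == ci
            pool = codes_by_cat[cat]
            codes[mask] = pool[rng.integers(0, len(pool), int(mask.sum()))]
        events = pd.DataFrame(
            dict(
                user_id=all_uid,
                timestamp=pd.to_datetime(all_t, unit="s"),
                action_code=codes,
                source=pd.NA,
            )
        )
        events = events.sort_values(["user_id", "timestamp"], kind="stable").reset_index(drop=True)
        events["file_order"] = np.arange(len(events))
    else:
        events = pd.DataFrame(columns=["user_id", "timestamp", "action_code", "source", "file_order"])

    truth_daily = pd.DataFrame(truth_days)
    if len(truth_daily):
        per_phys = truth_daily.groupby("physician_id")[["true_during_h", "true_outside_h"]].mean()
        cohort = dict(
            mean_during_h=float(per_phys["true_during_h"].mean()),
            mean_outside_h=float(per_phys["true_outside_h"].mean()),
            sd_during_h=float(per_phys["true_during_h"].std(ddof=1)),
            sd_outside_h=float(per_phys["true_outside_h"].std(ddof=1)),
            n_physician_days=int(len(truth_daily)),
        )
    else:
        cohort = {}
    ground_truth = dict(
        per_day=truth_days,
        per_physician_mu_during_h=dict(zip(eligible["physician_id"], mu_during.tolist())),
        per_physician_mu_outside_h=dict(zip(eligible["physician_id"], mu_outside.tolist())),
        cohort=cohort,
        category_shares_during=shares_during.tolist(),
        category_shares_outside=shares_outside.tolist(),
        n_truncated_budgets=n_truncated,
        n_events=int(len(events)),
    )
    if n_truncated:
        logger.warning("%d physician-day budgets exceeded block capacity and were truncated", n_truncated)
    return SimulatedStudy(
        roster=roster,
        visits=visits,
        action_map=action_map,
        events=events,
        ground_truth=ground_truth,
        n_truncated_budgets=n_truncated,
    )


def simulate_model_data(
    n_providers: int = 56,
    n_days: int = 19,
    beta: dict[str, float] | None = None,
    provider_sd: float = 0.8,
    day_sd: float = 0.24,
    resid_sd: float = 1.0,
    outcome: str = "outside",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Daily-summary-shaped data with known fixed and random components.

    Returns ``(daily, roster, truth)`` ready for
    :func:`ehrwow.mixedmodel.fit_mixed`: outcome = fixed linear predictor
    + provider intercepts + day intercepts + residual noise, with every
    generating value recorded in ``truth``.
    """
    if beta is None:
        beta = dict(const=2.0, age=-0.01, sex_female=-0.5, cfte=0.7)
        if outcome == "outside":
            beta["during_minutes"] = -0.003
    rng = np.random.default_rng(seed)
    pids = [f"P{i + 1:03d}" for i in range(n_providers)]
    age = np.clip(rng.normal(45.6, 9.9, n_providers), 30, 69)
    fte = np.clip(rng.normal(0.8, 0.2, n_providers), 0.5, 1.0)
    cfte = np.minimum(fte, np.clip(rng.normal(0.5, 0.2, n_providers), 0.1, 0.9))
    female = rng.random(n_providers) < 0.79
    roster = pd.DataFrame(
        dict(
            physician_id=pids,
            age=age,
            sex=np.where(female, "female", "male"),
            service_years=10.0,
            fte=fte,
            cfte=cfte,
            employment_status="regular",
        )
    )
    dates = pd.date_range("2019-09-02", periods=n_days, freq="B")
    prov_idx = np.repeat(np.arange(n_providers), n_days)
    day_idx = np.tile(np.arange(n_days), n_providers)
    u = rng.normal(0.0, provider_sd, n_providers)
    v = rng.normal(0.0, day_sd, n_days)
    hours_during = np.clip(rng.normal(4.4, 2.0, n_providers * n_days), 0.25, None)
    lin = (
        beta["const"]
        + beta.get("age", 0.0) * age[prov_idx]
        + beta.get("sex_female", 0.0) * female[prov_idx].astype(float)
        + beta.get("cfte", 0.0) * cfte[prov_idx]
        + beta.get("during_minutes", 0.0) * hours_during * 60.0
    )
    y = lin + u[prov_idx] + v[day_idx] + rng.normal(0.0, resid_sd, n_providers * n_days)
    daily = pd.DataFrame(
        dict(
            physician_id=np.asarray(pids, dtype=object)[prov_idx],
            date=[d.date() for d in dates[day_idx]],
            workday_flag=True,
            hours_during=hours_during if outcome != "during" else y,
            hours_outside=y if outcome == "outside" else 0.0,
        )
    )
    if outcome == "total":
        daily["hours_outside"] = y - daily["hours_during"]
    truth = dict(
        beta=beta,
        provider_sd=provider_sd,
        day_sd=day_sd,
        resid_sd=resid_sd,
        var_fixed=float(np.var(lin)),
        outcome=outcome,
    )
    return daily, roster, truth
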