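"""Cohort filtering, daily/cohort summaries, top-k actions, admin time."""

import numpy as np
import pandas as pd
import pytest

from ehrwow.aggregate import (
    admin_time,
    category_table,
    filter_cohort,
    high_users,
    summarize_cohort,
    summarize_daily,
    top_actions,
)
from ehrwow.io_schemas import CLINICAL_CATEGORIES
from ehrwow.windows import build_windows


def _roster(n, contingent=(), zero_cfte=()):
    return pd.DataFrame(
        dict(
            physician_id=[f"P{i}" for i in range(n)],
            age=45.0,
            sex="female",
            service_years=8.0,
            fte=1.0,
            cfte=[0.0 if i in zero_cfte else 0.5 for i in range(n)],
            employment_status=["contingent" if i in contingent else "regular" for i in range(n)],
        )
    )


def _daily(rows):
    """rows: (pid, date, hours_during, hours_outside); category detail in review."""
    recs = []
    for pid, date, h_d, h_o in rows:
        rec = dict(physician_id=pid, date=date, workday_flag=True, hours_during=h_d, hours_outside=h_o)
        for cat in CLINICAL_CATEGORIES:
            rec[f"hours_during_{cat}"] = h_d if cat == "review" else 0.0
            rec[f"hours_outside_{cat}"] = h_o if cat == "review" else 0.0
            rec[f"count_during_{cat}"] = 0
            rec[f"count_outside_{cat}"] = 0
        recs.append(rec)
    return pd.DataFrame(recs)


class TestFilterCohort:
    def test_62_candidates_minus_4_1_1_gives_56(self):
        roster = _roster(62, contingent=range(4), zero_cfte=[10])
        visits = pd.DataFrame(
            dict(
                physician_id=[f"P{i}" for i in range(62) if i != 20],
                start=pd.Timestamp("2019-09-02 08:00"),
                end=pd.Timestamp("2019-09-02 08:20"),
            )
        )
        eligible, tally = filter_cohort(roster, visits)
        assert len(eligible) == 56
        assert tally == {"contingent": 4, "zero_cfte": 1, "no_visits": 1}

    def test_all_eligible_is_identity(self):
        roster = _roster(5)
        visits = pd.DataFrame(
            dict(physician_id=[f"P{i}" for i in range(5)],
                 start=pd.Timestamp("2019-09-02 08:00"), end=pd.Timestamp("2019-09-02 08:20"))
        )
        eligible, tally = filter_cohort(roster, visits)
        assert eligible == [f"P{i}" for i in range(5)]
        assert sum(tally.values()) == 0

    def test_roster_disjoint_from_visits_excludes_everyone(self):
        roster = _roster(3)
        visits = pd.DataFrame(
            dict(physician_id=["Q1"], start=pd.Timestamp("2019-09-02 08:00"),
                 end=pd.Timestamp("2019-09-02 08:20"))
        )
        eligible, tally = filter_cohort(roster, visits)
        assert eligible == [] and tally["no_visits"] == 3


class TestSummarizeDaily:
    def _segmented(self, rows):
        """rows: (user, ts, dur, during_s, outside_s, seg, cat)"""
        return pd.DataFrame(
            dict(
                user_id=[r[0] for r in rows],
                timestamp=pd.to_datetime([r[1] for r in rows]),
                duration_s=[float(r[2]) for r in rows],
                during_s=[float(r[3]) for r in rows],
                outside_s=[float(r[4]) for r in rows],
                primary_segment=[r[5] for r in rows],
                clinical_category=[r[6] for r in rows],
            )
        )

    def test_single_minute_action_is_one_sixtieth_hour(self):
        seg = self._segmented([("P1", "2019-09-02 09:00", 60, 60, 0, "during", "review")])
        daily = summarize_daily(seg, build_windows(pd.DataFrame(columns=["physician_id", "start", "end"])))
        assert daily["hours_during"].iloc[0] == pytest.approx(1 / 60)
        assert daily["count_during_review"].iloc[0] == 1

    def test_visit_day_without_events_appears_with_zero_hours(self):
        visits = pd.DataFrame(
            dict(physician_id=["P9"], start=[pd.Timestamp("2019-09-03 08:00")],
                 end=[pd.Timestamp("2019-09-03 08:20")])
        )
        seg = self._segmented([("P1", "2019-09-02 09:00", 60, 60, 0, "during", "review")])
        daily = summarize_daily(seg, build_windows(visits))
        row = daily[daily["physician_id"] == "P9"]
        assert len(row) == 1
        assert row["hours_during"].iloc[0] == 0.0 and row["hours_outside"].iloc[0] == 0.0

    def test_hours_sum_over_categories(self, small_pipeline):
        daily = small_pipeline.daily
        cats = CLINICAL_CATEGORIES
        np.testing.assert_allclose(
            daily["hours_during"],
            sum(daily[f"hours_during_{c}"] for c in cats),
            atol=1e-9,
        )

    def test_global_conservation_against_retained_durations(self, small_pipeline):
        total_daily = (small_pipeline.daily["hours_during"] + small_pipeline.daily["hours_outside"]).sum()
        total_actions = small_pipeline.segmented["duration_s"].sum() / 3600.0
        assert total_daily == pytest.approx(total_actions, abs=1e-6)


class TestCategoryTable:
    def test_percent_columns_sum_to_100_within_rounding(self, small_pipeline):
        tab = category_table(small_pipeline.daily)
        body = tab[tab["category"] != "total"]
        for col in ("pct_during", "pct_outside", "pct_total"):
            assert abs(body[col].sum() - 100) <= 1 + 3  # integer rounding over 6 rows

    def test_total_row_is_sum_of_unrounded_components(self, small_pipeline):
        tab = category_table(small_pipeline.daily).set_index("category")
        per_phys = small_pipeline.daily.groupby("physician_id")["hours_during"].mean()
        assert tab.loc["total", "hours_during"] == pytest.approx(per_phys.mean(), abs=0.005)


class TestTopActions:
    def _seg(self, rows):
        return pd.DataFrame(
            dict(
                clinical_category=[r[0] for r in rows],
                action_code=[r[1] for r in rows],
                primary_segment=[r[2] for r in rows],
                outside_s=[float(r[3]) for r in rows],
                during_s=0.0,
            )
        )

    def test_single_action_tops_its_category(self):
        seg = self._seg([("review", "only_action", "outside", 120.0)])
        top = top_actions(seg, n_workdays=1, k=3)
        assert top["action_code"].iloc[0] == "only_action"
        assert top.set_index("clinical_category").loc["total", "minutes"] == 2.0

    def test_frequency_ties_break_by_minutes_then_code(self):
        seg = self._seg([
            ("review", "b_code", "outside", 100.0),
            ("review", "a_code", "outside", 100.0),
            ("review", "c_code", "outside", 200.0),
        ])
        top = top_actions(seg, n_workdays=1, k=2)
        assert top["action_code"].tolist()[:2] == ["c_code", "a_code"]

    def test_requires_positive_workdays(self):
        with pytest.raises(ValueError):
            top_actions(self._seg([]), n_workdays=0)


class TestAdminAndHighUsers:
    def test_admin_time_arithmetic(self):
        assert admin_time(100.0, 0.11, 22) == pytest.approx(0.5)
        assert admin_time(100.0, 0.0, 22) == 0.0

    def test_high_user_threshold_is_strict(self):
        daily = _daily([
            ("P1", "2019-09-02", 4.0, 0.4),
            ("P2", "2019-09-02", 4.0, 1.5),
            ("P3", "2019-09-02", 4.0, 1.6),
        ])
        ids, summary = high_users(daily, threshold=1.5)
        assert ids == ["P3"]
        assert summary.n_physicians == 1
        assert summary.mean_hours_outside == pytest.approx(1.6)

    def test_empty_subgroup_is_not_an_error(self):
        daily = _daily([("P1", "2019-09-02", 4.0, 0.1)])
        ids, summary = high_users(daily, threshold=1.5)
        assert ids == [] and summary.n_physicians == 0


class TestSummarizeCohort:
    def test_means_are_across_per_physician_workday_means(self):
        daily = _daily([
            ("P1", "2019-09-02", 2.0, 0.0),
            ("P1", "2019-09-03", 4.0, 1.0),
            ("P2", "2019-09-02", 6.0, 2.0),
        ])
        c = summarize_cohort(daily)
        assert c.mean_hours_during == pytest.approx((3.0 + 6.0) / 2)
        assert c.mean_hours_outside == pytest.approx((0.5 + 2.0) / 2)
        assert c.n_workdays == 3
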