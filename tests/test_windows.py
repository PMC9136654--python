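"""Clinic-window construction and the during/outside decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ehrwow.windows import build_windows, segment_action, segment_actions

from .conftest import brute_force_during_seconds, random_window_instance


def _visits(rows):
    return pd.DataFrame(
        dict(
            physician_id=[r[0] for r in rows],
            start=pd.to_datetime([r[1] for r in rows]),
            end=pd.to_datetime([r[2] for r in rows]),
        )
    )


class TestBuildWindows:
    def test_consecutive_visits_merge_into_one_window(self):
        v = _visits([
            ("P1", "2019-09-02 09:00", "2019-09-02 09:20"),
            ("P1", "2019-09-02 09:20", "2019-09-02 09:40"),
        ])
        wins = build_windows(v, 30)
        starts, ends = wins.intervals_for("P1")
        assert len(starts) == 1
        assert pd.Timestamp(starts[0], unit="s") == pd.Timestamp("2019-09-02 08:30")
        assert pd.Timestamp(ends[0], unit="s") == pd.Timestamp("2019-09-02 10:10")

    def test_distant_visits_stay_separate(self):
        v = _visits([
            ("P1", "2019-09-02 09:00", "2019-09-02 09:20"),
            ("P1", "2019-09-02 14:00", "2019-09-02 14:20"),
        ])
        starts, ends = build_windows(v, 30).intervals_for("P1")
        assert len(starts) == 2
        assert pd.Timestamp(ends[0], unit="s") == pd.Timestamp("2019-09-02 09:50")
        assert pd.Timestamp(starts[1], unit="s") == pd.Timestamp("2019-09-02 13:30")

    def test_no_visits_means_everything_outside(self):
        wins = build_windows(_visits([]), 30)
        during, outside, seg = segment_action(pd.Timestamp("2019-09-02 09:00"), 600.0, wins, "P1")
        assert during == 0.0 and outside == 600.0 and seg == "outside"

    def test_window_assigned_to_start_date_of_earliest_visit(self):
        v = _visits([("P1", "2019-09-02 23:00", "2019-09-03 00:30")])
        wins = build_windows(v, 30)
        assert wins.per_day["date"].iloc[0] == pd.Timestamp("2019-09-02").date()

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            build_windows(_visits([]), -1)


class TestSegmentAction:
    WINS = None

    @classmethod
    def setup_class(cls):
        cls.WINS = build_windows(
            _visits([("P1", "2019-09-02 09:00", "2019-09-02 09:40")]), 30
        )  # window 08:30-10:10

    def test_fully_contained_action(self):
        during, outside, seg = segment_action(pd.Timestamp("2019-09-02 09:00"), 60.0, self.WINS, "P1")
        assert (during, outside, seg) == (60.0, 0.0, "during")

    def test_straddling_action_splits_proportionally(self):
        during, outside, seg = segment_action(pd.Timestamp("2019-09-02 10:09"), 120.0, self.WINS, "P1")
        assert (during, outside) == (60.0, 60.0)
        assert seg == "during"  # start timestamp decides the frequency label

    def test_event_at_exact_window_end_is_outside(self):
        during, outside, seg = segment_action(pd.Timestamp("2019-09-02 10:10"), 60.0, self.WINS, "P1")
        assert (during, outside, seg) == (0.0, 60.0, "outside")

    def test_start_policy_assigns_whole_duration(self):
        df = pd.DataFrame(
            dict(user_id=["P1"], timestamp=[pd.Timestamp("2019-09-02 10:09")], duration_s=[120.0])
        )
        seg = segment_actions(df, self.WINS, straddle_policy="start")
        assert seg["during_s"].iloc[0] == 120.0 and seg["outside_s"].iloc[0] == 0.0


class TestProperties:
    def test_bruteforce_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            wins, t, d = random_window_instance(rng)
            df = pd.DataFrame(
                dict(user_id=["P1"], timestamp=[pd.to_datetime(t, unit="s")], duration_s=[float(d)])
            )
            got = float(segment_actions(df, wins)["during_s"].iloc[0])
            starts, ends = wins.intervals_for("P1")
            expected = brute_force_during_seconds(t, d, starts, ends)
            assert got == pytest.approx(expected, abs=1e-6)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        visit_start=st.integers(0, 80_000),
        visit_len=st.integers(60, 20_000),
        t_off=st.integers(-10_000, 100_000),
        dur=st.integers(0, 10_000),
        margin=st.sampled_from([0.0, 10.0, 30.0]),
    )
    def test_conservation_during_plus_outside_equals_duration(
        self, visit_start, visit_len, t_off, dur, margin
    ):
        base = pd.Timestamp("2019-09-02").value // 10**9
        v = pd.DataFrame(
            dict(
                physician_id=["P1"],
                start=[pd.to_datetime(base + visit_start, unit="s")],
                end=[pd.to_datetime(base + visit_start + visit_len, unit="s")],
            )
        )
        wins = build_windows(v, margin)
        df = pd.DataFrame(
            dict(user_id=["P1"], timestamp=[pd.to_datetime(base + t_off, unit="s")], duration_s=[float(dur)])
        )
        seg = segment_actions(df, wins)
        during, outside = float(seg["during_s"].iloc[0]), float(seg["outside_s"].iloc[0])
        assert during >= 0.0 and outside >= 0.0
        assert during + outside == pytest.approx(float(dur), abs=1e-6)

    def test_during_time_monotone_in_margin(self):
        rng = np.random.default_rng(77)
        base = pd.Timestamp("2019-09-02").value // 10**9
        v = _visits([("P1", "2019-09-02 09:00", "2019-09-02 10:00"),
                     ("P1", "2019-09-02 13:00", "2019-09-02 14:00")])
        actions = pd.DataFrame(
            dict(
                user_id="P1",
                timestamp=pd.to_datetime(base + rng.integers(0, 86_400, 200), unit="s"),
                duration_s=rng.integers(0, 3_600, 200).astype(float),
            )
        ).sort_values("timestamp")
        totals = []
        for margin in (0, 10, 30, 60, 120):
            seg = segment_actions(actions, build_windows(v, margin))
            totals.append(seg["during_s"].sum())
        assert totals == sorted(totals)
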