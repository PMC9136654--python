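"""Shared fixtures: small simulated cohorts and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ehrwow.synthetic_data import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down cohort: 6 physicians, 2 weeks, sparse event stream."""
    return GeneratorConfig(
        n_physicians=6,
        n_contingent=2,
        n_zero_cfte=1,
        n_no_visits=1,
        period_days=14,
        mean_gap_s=45.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    from ehrwow.pipeline import run_pipeline

    return run_pipeline(
        small_study.events,
        small_study.visits,
        small_study.roster,
        small_study.action_map,
        fit_models=False,
    )


def brute_force_during_seconds(t_epoch: int, duration_s: int, starts: np.ndarray, ends: np.ndarray) -> float:
    """Assign each whole second of [t, t+d) to during/outside by point testing."""
    secs = t_epoch + np.arange(int(duration_s))
    inside = np.zeros(int(duration_s), dtype=bool)
    for s, e in zip(starts, ends):
        inside |= (secs >= s) & (secs < e)
    return float(inside.sum())


def random_window_instance(rng: np.random.Generator):
    """A random physician-day of visits plus one action, integer seconds."""
    from ehrwow.windows import build_windows

    base = pd.Timestamp("2019-09-02").value // 10**9
    n_visits = int(rng.integers(1, 4))
    starts = rng.integers(0, 50_000, n_visits)
    lengths = rng.integers(300, 7200, n_visits)
    visits = pd.DataFrame(
        dict(
            physician_id="P1",
            start=pd.to_datetime(base + starts, unit="s"),
            end=pd.to_datetime(base + starts + lengths, unit="s"),
        )
    )
    margin = float(rng.choice([0.0, 15.0, 30.0]))
    wins = build_windows(visits, margin)
    t = base + int(rng.integers(-5_000, 70_000))
    d = int(rng.integers(0, 3_000))
    return wins, t, d
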