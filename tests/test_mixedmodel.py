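"""Crossed random-effects fitting, the R² partition, and diagnostics."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from ehrwow.mixedmodel import ModelSpec, fit_mixed, normality_check, r2_partition
from ehrwow.synthetic_data import simulate_model_data


class TestModelSpec:
    def test_outside_model_requires_during_minutes(self):
        spec = ModelSpec(outcome="outside")
        assert "during_minutes" in spec.fixed_terms
        with pytest.raises(ValueError):
            ModelSpec(outcome="outside", fixed_terms=("age",))

    def test_other_models_reject_during_minutes(self):
        with pytest.raises(ValueError):
            ModelSpec(outcome="during", fixed_terms=("during_minutes", "age"))

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(outcome="weekend")


class TestR2Partition:
    def test_forced_arithmetic(self):
        # fixed-predictor variance 1, random 4, residual 5 -> 10/40/50 %
        pred = np.array([0.0, 2.0])  # variance 1
        r2f, r2r, r2t = r2_partition(pred, {"provider": 3.0, "day": 1.0, "residual": 5.0})
        assert (r2f, r2r, r2t) == (10.0, 40.0, 50.0)

    def test_null_model_has_zero_fixed_share(self):
        r2f, _, _ = r2_partition(np.full(10, 3.7), {"provider": 1.0, "day": 0.0, "residual": 1.0})
        assert r2f == pytest.approx(0.0, abs=1e-12)

    def test_zero_total_variance_errors(self):
        with pytest.raises(ValueError):
            r2_partition(np.zeros(5), {"provider": 0.0, "day": 0.0, "residual": 0.0})

    def test_partition_invariant_to_affine_outcome_rescaling(self):
        daily, roster, _ = simulate_model_data(n_providers=20, n_days=8, seed=4)
        res = fit_mixed(daily, roster, ModelSpec(outcome="outside"))
        scaled = daily.copy()
        scaled["hours_outside"] = 3.0 * scaled["hours_outside"] + 7.0
        res2 = fit_mixed(scaled, roster, ModelSpec(outcome="outside"))
        assert res2.r2_total == pytest.approx(res.r2_total, abs=0.5)


class TestFitMixed:
    def test_no_random_terms_reduces_to_ols(self):
        daily, roster, _ = simulate_model_data(n_providers=15, n_days=6, seed=9)
        res = fit_mixed(daily, roster, ModelSpec(outcome="outside", random_terms=()))
        import statsmodels.api as sm

        from ehrwow.mixedmodel import build_model_frame

        frame = build_model_frame(daily, roster, ModelSpec(outcome="outside"))
        X = sm.add_constant(frame[["during_minutes", "age", "sex_female", "cfte"]])
        ols = sm.OLS(frame["y"], X).fit()
        for name, ref_val in zip(["const", "during_minutes", "age", "sex_female", "cfte"], ols.params):
            assert res.params[name] == pytest.approx(ref_val, abs=1e-6)

    def test_constant_outcome_degenerates_cleanly(self):
        daily, roster, _ = simulate_model_data(n_providers=5, n_days=4, seed=2)
        daily["hours_outside"] = 1.25
        res = fit_mixed(daily, roster, ModelSpec(outcome="outside"))
        assert res.params["const"] == 1.25
        assert res.vc == {"provider": 0.0, "day": 0.0, "residual": 0.0}
        assert res.singular

    def test_zero_noise_zero_random_recovers_coefficients_exactly(self):
        beta = dict(const=1.0, age=-0.02, sex_female=0.3, cfte=1.1, during_minutes=-0.002)
        daily, roster, _ = simulate_model_data(
            n_providers=25, n_days=8, beta=dict(beta), provider_sd=0.0, day_sd=0.0,
            resid_sd=1e-8, seed=5,
        )
        res = fit_mixed(daily, roster, ModelSpec(outcome="outside", random_terms=()))
        for name, val in beta.items():
            assert res.params[name] == pytest.approx(val, abs=1e-4)

    def test_single_provider_flags_inestimable_component(self):
        daily, roster, _ = simulate_model_data(n_providers=1, n_days=8, seed=6)
        res = fit_mixed(daily, roster, ModelSpec(outcome="during", fixed_terms=("age",)))
        assert res.singular
        assert any("single provider" in n for n in res.notes)

    def test_near_zero_random_variance_gives_near_zero_random_r2(self):
        daily, roster, _ = simulate_model_data(
            n_providers=30, n_days=10, provider_sd=0.0, day_sd=0.0, resid_sd=0.5, seed=7
        )
        res = fit_mixed(daily, roster, ModelSpec(outcome="outside"))
        assert res.r2_random < 5.0

    def test_weekly_aggregation_uses_iso_weeks(self):
        daily, roster, _ = simulate_model_data(n_providers=10, n_days=15, seed=8)
        res = fit_mixed(daily, roster, ModelSpec(outcome="outside", aggregation="weekly"))
        # 15 business days span 3 ISO weeks
        assert res.n_obs == 30

    def test_variance_recovery_within_2se_over_seeds(self):
        prov, day = [], []
        for seed in range(4):
            daily, roster, truth = simulate_model_data(
                n_providers=40, n_days=15, provider_sd=0.8, day_sd=0.24, resid_sd=1.0, seed=100 + seed
            )
            res = fit_mixed(daily, roster, ModelSpec(outcome="outside"))
            prov.append(res.vc_sd["provider"])
            day.append(res.vc_sd["day"])
        se_p = np.std(prov, ddof=1) / np.sqrt(len(prov))
        se_d = np.std(day, ddof=1) / np.sqrt(len(day))
        assert abs(np.mean(prov) - 0.8) <= max(2 * se_p, 0.1)
        assert abs(np.mean(day) - 0.24) <= max(2 * se_d, 0.1)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R unavailable")
def test_crossed_fit_matches_lme4_oracle(tmp_path):
    """Independent oracle: lme4's REML fit of the same crossed model."""
    daily, roster, _ = simulate_model_data(n_providers=20, n_days=10, seed=12)
    res = fit_mixed(daily, roster, ModelSpec(outcome="outside", fixed_terms=("during_minutes", "age")))

    from ehrwow.mixedmodel import build_model_frame

    frame = build_model_frame(daily, roster, ModelSpec(outcome="outside"))
    csv = tmp_path / "frame.csv"
    frame.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        library(lme4)
        d <- read.csv("{csv}", colClasses=c(provider="character", time="character"))
        m <- lmer(y ~ during_minutes + age + (1|provider) + (1|time), data=d, REML=TRUE)
        vc <- as.data.frame(VarCorr(m))
        cat(fixef(m)["during_minutes"], fixef(m)["age"],
            vc$vcov[vc$grp=="provider"], vc$vcov[vc$grp=="time"], vc$vcov[vc$grp=="Residual"], sep=",")
    """))
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=120)
    assert out.returncode == 0, out.stderr
    b_dm, b_age, v_prov, v_time, v_resid = map(float, out.stdout.strip().split(","))
    assert res.params["during_minutes"] == pytest.approx(b_dm, abs=1e-4)
    assert res.params["age"] == pytest.approx(b_age, abs=1e-4)
    assert res.vc["provider"] == pytest.approx(v_prov, rel=0.02, abs=1e-3)
    assert res.vc["day"] == pytest.approx(v_time, rel=0.05, abs=1e-3)
    assert res.vc["residual"] == pytest.approx(v_resid, rel=0.02, abs=1e-3)


class TestNormalityCheck:
    def test_normal_sample_recommends_no_transform(self):
        rng = np.random.default_rng(1)
        report = normality_check(rng.normal(0, 1, 1000))
        assert report["recommendation"] == "none"
        assert not report["degenerate"]

    def test_right_skewed_sample_recommends_log1p(self):
        rng = np.random.default_rng(2)
        report = normality_check(rng.exponential(1.0, 1000))
        assert report["recommendation"] == "log1p"
        assert report["skewness"] > 1.0

    def test_constant_residuals_flagged_degenerate(self):
        report = normality_check(np.full(50, 2.0))
        assert report["degenerate"]
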