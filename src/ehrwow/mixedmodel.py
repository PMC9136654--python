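"""Crossed random-effects models of daily (or weekly) EHR time.

The outcome is a physician-day (or physician-week) quantity — EHR hours
during, outside, or in total — modelled as

    y_ij = x_i' beta + u_i + v_j + e_ij

with fixed effects for age, sex and clinical FTE (plus, for the outside
model only, the same day's during-hours in minutes), and independent
random intercepts u_i ~ N(0, s2_provider) for provider and
v_j ~ N(0, s2_day) for calendar day (ISO week under weekly aggregation).
Provider and day are crossed, not nested: every day is shared by many
providers.  Estimation is REML via statsmodels MixedLM with the two
random factors as variance components of a single grouping.

Model fit is summarized by a variance partition: the share of total
variance explained by the fixed-effect linear predictor (fixed R²), by
the random intercepts (random R²), and their sum (total R²), where total
variance = var(x'beta) + s2_provider + s2_day + s2_residual.  The two
shares are additive by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ModelSpec",
    "MixedModelResult",
    "build_model_frame",
    "fit_mixed",
    "r2_partition",
    "normality_check",
]

OUTCOMES = ("during", "outside", "total")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, covariates, random structure, aggregation."""

    outcome: str = "outside"
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = ("provider", "day")
    aggregation: str = "daily"
    transform: str = "none"

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if self.aggregation not in ("daily", "weekly"):
            raise ValueError("aggregation must be 'daily' or 'weekly'")
        if self.transform not in ("none", "log1p"):
            raise ValueError("transform must be 'none' or 'log1p'")
        terms = self.fixed_terms or self.default_fixed_terms(self.outcome)
        object.__setattr__(self, "fixed_terms", tuple(terms))
        # the during-hours predictor belongs to the outside model alone
        if self.outcome == "outside" and "during_minutes" not in self.fixed_terms:
            raise ValueError("the outside model includes during_minutes as a fixed term")
        if self.outcome != "outside" and "during_minutes" in self.fixed_terms:
            raise ValueError("during_minutes is a fixed term of the outside model only")

    @staticmethod
    def default_fixed_terms(outcome: str) -> tuple[str, ...]:
        base = ("age", "sex_female", "cfte")
        return ("during_minutes",) + base if outcome == "outside" else base


@dataclass
class MixedModelResult:
    """Coefficients, variance components and the R² partition of one fit."""

    spec: ModelSpec
    params: dict[str, float]
    bse: dict[str, float]
    vc: dict[str, float]           # variances: provider, day, residual
    vc_sd: dict[str, float]
    r2_fixed: float
    r2_random: float
    r2_total: float
    n_obs: int
    converged: bool = True
    singular: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(
            outcome=self.spec.outcome,
            aggregation=self.spec.aggregation,
            transform=self.spec.transform,
            fixed_terms=list(self.spec.fixed_terms),
            coefficients={k: dict(estimate=v, se=self.bse.get(k)) for k, v in self.params.items()},
            variance_components={k: dict(variance=v, sd=self.vc_sd[k]) for k, v in self.vc.items()},
            r2_percent=dict(fixed=self.r2_fixed, random=self.r2_random, total=self.r2_total),
            n_obs=self.n_obs,
            converged=self.converged,
            singular=self.singular,
            notes=self.notes,
        )


def build_model_frame(daily: pd.DataFrame, roster: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Assemble the modelling frame: outcome, covariates, provider/time factors.

    Sex enters as an indicator with male as the reference level.  Under
    weekly aggregation hours are summed per (provider, ISO week) and the
    week replaces the day as the crossed temporal factor.
    """
    d = daily[daily["workday_flag"]].copy()
    d["provider"] = d["physician_id"].astype(str)
    if spec.aggregation == "daily":
        d["time"] = d["date"].astype(str)
        agg = d[["provider", "time", "hours_during", "hours_outside"]]
    else:
        iso = pd.to_datetime(d["date"].astype(str)).dt.isocalendar()
        d["time"] = iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)
        agg = (
            d.groupby(["provider", "time"], as_index=False)[["hours_during", "hours_outside"]].sum()
        )
    agg = agg.copy()
    agg["y_during"] = agg["hours_during"]
    agg["y_outside"] = agg["hours_outside"]
    agg["y_total"] = agg["hours_during"] + agg["hours_outside"]
    agg["during_minutes"] = agg["hours_during"] * 60.0

    cov = roster.copy()
    cov["provider"] = cov["physician_id"].astype(str)
    cov["sex_female"] = (cov["sex"] == "female").astype(float)
    frame = agg.merge(cov[["provider", "age", "sex_female", "cfte"]], on="provider", how="inner")
    y = frame[f"y_{spec.outcome}"].astype(float)
    frame["y"] = np.log1p(y) if spec.transform == "log1p" else y
    missing = frame[list(spec.fixed_terms)].isna().any()
    if missing.any():
        raise ValueError(f"incomplete covariates: {list(missing[missing].index)}")
    return frame


def r2_partition(
    fixed_predictor: np.ndarray,
    vc: dict[str, float],
) -> tuple[float, float, float]:
    """Variance partition in percent: (fixed, random, total).

    fixed share = var(x'beta) / T; random share = (provider + day) / T;
    T = var(x'beta) + provider + day + residual.  The partition is
    invariant to affine rescaling of the outcome.
    """
    var_f = float(np.var(np.asarray(fixed_predictor, dtype=float)))
    var_random = float(sum(v for k, v in vc.items() if k != "residual"))
    total = var_f + var_random + float(vc.get("residual", 0.0))
    if total <= 0:
        raise ValueError("zero total variance; R² partition undefined")
    r2f = 100.0 * var_f / total
    r2r = 100.0 * var_random / total
    return r2f, r2r, r2f + r2r


def fit_mixed(daily: pd.DataFrame, roster: pd.DataFrame, spec: ModelSpec) -> MixedModelResult:
    """REML fit of the crossed random-intercept model for one outcome.

    With ``random_terms=()`` the model degenerates to ordinary least
    squares (a useful cross-check: shared coefficients agree).  A
    variance component estimated at (or forced to) the boundary 0 flags
    the fit as singular rather than erroring.
    """
    frame = build_model_frame(daily, roster, spec)
    random_terms = list(spec.random_terms)
    notes_pre: list[str] = []
    if "provider" in random_terms and frame["provider"].nunique() < 2:
        random_terms.remove("provider")
        notes_pre.append("provider variance inestimable (single provider)")
    if "day" in random_terms and frame["time"].nunique() < 2:
        random_terms.remove("day")
        notes_pre.append("day variance inestimable (single time point)")
    terms = list(spec.fixed_terms)
    X = sm.add_constant(frame[terms].astype(float), has_constant="add")
    y = frame["y"].to_numpy(dtype=float)
    names = ["const"] + terms
    notes: list[str] = []

    if float(np.var(y)) == 0.0:
        # constant outcome: intercept = the constant, everything else 0
        params = {n: 0.0 for n in names}
        params["const"] = float(y[0]) if len(y) else 0.0
        vc = {"provider": 0.0, "day": 0.0, "residual": 0.0}
        return MixedModelResult(
            spec=spec, params=params, bse={n: 0.0 for n in names},
            vc=vc, vc_sd={k: 0.0 for k in vc}, r2_fixed=0.0, r2_random=0.0, r2_total=0.0,
            n_obs=len(frame), converged=True, singular=True, notes=["constant outcome"],
        )

    if not random_terms:
        ols = sm.OLS(y, X).fit()
        vc = {"provider": 0.0, "day": 0.0, "residual": float(ols.scale)}
        pred = ols.fittedvalues
        r2f, r2r, r2t = r2_partition(np.asarray(pred), vc)
        return MixedModelResult(
            spec=spec,
            params=dict(zip(names, ols.params)),
            bse=dict(zip(names, ols.bse)),
            vc=vc,
            vc_sd={k: float(np.sqrt(v)) for k, v in vc.items()},
            r2_fixed=r2f, r2_random=r2r, r2_total=r2t,
            n_obs=len(frame), converged=True, singular=bool(notes_pre),
            notes=notes_pre + ["OLS (no random terms)"],
        )

    data = frame.copy()
    data["_group"] = 1
    vc_formula = {}
    if "provider" in random_terms:
        vc_formula["provider"] = "0 + C(provider)"
    if "day" in random_terms:
        vc_formula["day"] = "0 + C(time)"
    formula = "y ~ " + " + ".join(terms) if terms else "y ~ 1"
    model = smf.mixedlm(formula, data, groups="_group", vc_formula=vc_formula)
    with warnings.catch_warnings():
        # non-convergence is reported through the `converged` flag; near a
        # variance boundary the default optimizer can stall, so retry with
        # gradient-free/quasi-Newton methods before giving up
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
        for method in ("lbfgs", "powell"):
            if fit.converged:
                break
            retry = model.fit(reml=True, method=method)
            if retry.converged:
                fit = retry
    vc_names = list(model.exog_vc.names)  # statsmodels orders components by this list
    vcomp = dict(zip(vc_names, fit.vcomp))
    vc = {
        "provider": float(max(vcomp.get("provider", 0.0), 0.0)),
        "day": float(max(vcomp.get("day", 0.0), 0.0)),
        "residual": float(fit.scale),
    }
    notes.extend(notes_pre)
    singular = bool(notes_pre) or any(
        vcomp.get(k, 0.0) <= 1e-10 for k in ("provider", "day") if k in vc_formula
    )
    if singular and not notes_pre:
        notes.append("variance component at boundary 0")
    fe_names = list(fit.fe_params.index)
    params = {("const" if n == "Intercept" else n): float(fit.fe_params[n]) for n in fe_names}
    bse = {("const" if n == "Intercept" else n): float(fit.bse_fe[n]) for n in fe_names}
    beta = np.array([params["const"]] + [params[t] for t in terms])
    pred = X.to_numpy(dtype=float) @ beta
    r2f, r2r, r2t = r2_partition(pred, vc)
    return MixedModelResult(
        spec=spec, params=params, bse=bse, vc=vc,
        vc_sd={k: float(np.sqrt(v)) for k, v in vc.items()},
        r2_fixed=r2f, r2_random=r2r, r2_total=r2t,
        n_obs=len(frame), converged=bool(fit.converged), singular=singular, notes=notes,
    )


def normality_check(residuals: np.ndarray, skew_threshold: float = 1.0) -> dict:
    """Residual-normality diagnostics with an advisory transform recommendation.

    Reports skewness, excess kurtosis, and observed-vs-normal quantiles;
    recommends ``log1p`` when |skewness| exceeds ``skew_threshold``.
    Advisory only: nothing is transformed automatically.
    """
    r = np.asarray(residuals, dtype=float)
    r = r[~np.isnan(r)]
    if len(r) < 3 or np.var(r) == 0.0:
        return dict(n=int(len(r)), degenerate=True, recommendation="none",
                    skewness=0.0, excess_kurtosis=0.0, quantiles={})
    skew = float(stats.skew(r))
    kurt = float(stats.kurtosis(r))
    probs = (0.05, 0.25, 0.50, 0.75, 0.95)
    z = stats.norm.ppf(probs)
    observed = np.quantile(r, probs)
    expected = np.mean(r) + np.std(r) * z
    quantiles = {
        f"p{int(100 * p)}": dict(observed=float(o), normal=float(e))
        for p, o, e in zip(probs, observed, expected)
    }
    return dict(
        n=int(len(r)),
        degenerate=False,
        skewness=skew,
        excess_kurtosis=kurt,
        quantiles=quantiles,
        recommendation="log1p" if abs(skew) > skew_threshold else "none",
    )
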