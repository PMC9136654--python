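"""Fit the crossed random-effects models on the simulated cohort.

Models daily and weekly EHR hours (during / outside / total) with fixed
effects for age, sex and clinical FTE (plus during-minutes for the
outside model) and crossed random intercepts for provider and day,
reporting coefficients, variance components and the fixed/random/total
R² partition.  Writes results/models/model_results.json.

Run from the repository root:  python analysis/03_fit_mixed_models.py
"""

import json
from pathlib import Path

import pandas as pd

from ehrwow.io_schemas import read_roster
from ehrwow.mixedmodel import ModelSpec, fit_mixed, normality_check

out = Path("results/models")
out.mkdir(parents=True, exist_ok=True)

daily = pd.read_csv("scratch/pipeline/daily_summary.csv", parse_dates=["date"])
daily["date"] = daily["date"].dt.date
roster = read_roster("scratch/data/roster.csv")

results = []
for aggregation in ("daily", "weekly"):
    for outcome in ("during", "outside", "total"):
        spec = ModelSpec(outcome=outcome, aggregation=aggregation)
        res = fit_mixed(daily, roster, spec)
        results.append(res)
        print(f"{outcome:8s} ({aggregation}):  "
              f"R² fixed {res.r2_fixed:5.1f}%  random {res.r2_random:5.1f}%  total {res.r2_total:5.1f}%   "
              f"provider SD {res.vc_sd['provider']:.2f}  day SD {res.vc_sd['day']:.2f}"
              f"{'' if res.converged else '  [not converged]'}")

y = daily.loc[daily["workday_flag"], "hours_outside"]
diag = normality_check((y - y.mean()).to_numpy())
print(f"\noutside-hours distribution: skewness {diag['skewness']:.2f} "
      f"-> transform recommendation: {diag['recommendation']} (advisory)")

with open(out / "model_results.json", "w") as fh:
    json.dump(dict(models=[r.to_dict() for r in results], outside_normality=diag), fh, indent=1)
print(f"wrote {out / 'model_results.json'}")
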