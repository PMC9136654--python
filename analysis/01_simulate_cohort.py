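"""Simulate the synthetic study cohort.

Generates one month of synthetic audit-log data at the default study
conditions — 62 rostered physicians (56 eligible), weekday visit sessions,
a 290-code action vocabulary, ~1.5 M time-stamped events — and writes the
four observed input CSVs plus the ground-truth sidecar under
scratch/data/ (the raw event log is large, so it stays out of results/).

Run from the repository root:  python analysis/01_simulate_cohort.py [seed]
"""

import sys
from pathlib import Path

from ehrwow.synthetic_data import GeneratorConfig, simulate_cohort

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
out_dir = Path("scratch/data")

config = GeneratorConfig(seed=seed)
study = simulate_cohort(config)
paths = study.write(out_dir)

truth = study.ground_truth["cohort"]
print(f"simulated cohort (seed={seed}):")
print(f"  events:            {len(study.events):,}")
print(f"  scheduled visits:  {len(study.visits):,}")
print(f"  physician-days:    {truth['n_physician_days']}")
print(f"  true during-hours: {truth['mean_during_h']:.2f} (SD {truth['sd_during_h']:.2f}) per workday")
print(f"  true outside-hours:{truth['mean_outside_h']:.2f} (SD {truth['sd_outside_h']:.2f}) per workday")
print(f"  truncated budgets: {study.n_truncated_budgets}")
print(f"wrote: {', '.join(str(p) for p in paths.values())}")
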