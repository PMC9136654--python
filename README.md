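# ehrwow — EHR time outside scheduled clinic hours, from raw audit logs

Clinicians do a substantial share of their electronic-health-record (EHR)
work after hours — "work outside work" — and quantifying it from raw audit
logs requires three things most vendor dashboards hide: a defensible
per-action time estimate, a defensible definition of "work hours", and a
transparent action taxonomy.  `ehrwow` is an analysis pipeline for
clinical-informatics researchers that implements all three against each
physician's *actual visit schedule* rather than fixed clock times:

1. **Access time.** The audit log records instants, not durations.  The
   time attributed to an action is the inter-event delta — the gap to the
   same user's next logged action (zero for the last one).  Gaps longer
   than an idle cutoff (default > 15 min, strict) are treated as idle and
   removed.
2. **Scheduled clinic hours.** Per physician-day, the union of half-open
   intervals `[visit.start − m, visit.end + m)` over that day's scheduled
   visits, with margin m = 30 min; touching expansions merge.  Each
   action's occupancy `[t, t + d)` is intersected with the windows, giving
   a during/outside split with exact conservation (`during + outside = d`).
3. **Taxonomy.** Every action code maps to one of six clinical categories
   (review, documentation, inbox, orders, log-in, logout) and a fixed
   four-way conceptual projection (data review / data entry / data
   transmission / other).

On top of these the package builds per-physician-per-workday summaries,
cohort tables (hours and column-percents by category × segment, top-k
actions outside clinic hours, high-user subgroup) and fits crossed
random-effects models

    y_ij = x_i' β + u_i + v_j + ε_ij,   u_i ~ N(0, σ²_provider),  v_j ~ N(0, σ²_day)

of daily/weekly EHR hours (REML, via statsmodels), reporting the
fixed/random/total R² variance partition.  A seedable synthetic-cohort
generator emits a full study — roster, visit schedules, a 290-code action
vocabulary, ~1.5 M-event access log, and a ground-truth sidecar — so every
stage is testable without any hospital data.

## Worked example

```bash
python analysis/01_simulate_cohort.py 1     # ~1.5 M events under scratch/data/
python analysis/02_run_pipeline.py          # tables under results/pipeline/
python analysis/03_fit_mixed_models.py      # results/models/model_results.json
```

The second step prints (seed 1):

```
cohort: 56 eligible physicians (excluded: {'contingent': 4, 'zero_cfte': 1, 'no_visits': 1}), 1078 physician-workdays
idle filter removed 4,231 of 1,513,873 actions
EHR hours per physician per workday:
  during clinic hours:  estimated 4.12 (SD 1.61)  | ground truth 4.12
  outside clinic hours: estimated 0.90 (SD 0.69)  | ground truth 0.90
  administrative time available: 0.65 h/workday
high users (>1.5 h outside): 11 physicians
```

Reading: of 62 rostered physicians, 56 are study-eligible; over 1078
physician-workdays the pipeline attributes on average 4.12 h of EHR time
per workday to scheduled clinic hours and 0.90 h outside them — matching,
to the second, the per-day time budgets the generator actually encoded in
the event stream (the estimates are *exact* because every within-burst
gap survives the idle filter and every idle separation exceeds it).  The
category table shows ~72–78 % of time in chart review in both segments,
and the crossed random-effects fit of outside-hours attributes most
explained variance to between-provider differences.

The same pipeline runs on real exports via the CLI:

```bash
ehrwow run --log access_log.csv --visits visits.csv --roster roster.csv \
           --action-map action_map.csv --config run.yaml --out out/
ehrwow simulate --out sim/ --seed 7
```

Every analysis convention (idle cutoff, window margin, straddle policy,
workday rule, top-k, thresholds, model spec) is a flat YAML config key;
see `ehrwow.config.PipelineConfig`.

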