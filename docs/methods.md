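# Methods

## The measurement problem

EHR audit logs record discrete time-stamped user actions — chart views,
note edits, order entries, log-ins — but not how long anything took.  The
pipeline estimates and attributes that time in three steps, each a stated
convention rather than a hidden heuristic.

### Access time from inter-event deltas

The duration of an action is the gap to the same user's next logged
action; a user's final action gets zero.  Deltas are computed strictly
within user (never across users) and across day boundaries; the idle
filter then removes implausibly long gaps.  The cutoff is > 15 minutes,
*strict*: a gap of exactly 15 minutes is retained, 15 min + 1 s is
removed.  By default a removed action disappears from both time totals
and frequency counts; `idle_policy: zero_duration` instead keeps the
event for counting at zero attributed time (the source description of
"removed" does not distinguish the two readings, so both are supported
and the literal one is the default).  Useful invariants, all tested:
before filtering, per-user durations sum exactly to the user's
first-to-last span; filtering is idempotent; retained time is monotone in
the cutoff.

### Scheduled clinic hours and the during/outside split

"Work hours" are not clock hours: they are built per physician-day from
the *actual scheduled visits*, as the union of `[start − 30 min,
end + 30 min)` over visits, with overlapping or touching margins merged
(so back-to-back appointments produce one window, and the margins capture
preparatory/closing work).  Conventions:

- **Half-open intervals** `[start, end)`: an event at a window's exact end
  is outside.  No boundary second is counted twice.
- **Straddling actions** are split proportionally by clock time between
  the two segments (durations are conserved exactly); frequency counts
  use the segment containing the action's *start* timestamp, so counts
  stay integral.  `straddle_policy: start` assigns the whole duration to
  the start segment instead — the original convention is not stated, so
  both are available.
- **Midnight**: a window generated by an evening visit may cross
  midnight and belongs to the visit's start date; segmentation uses each
  physician's full merged window set, so late actions are decomposed
  correctly regardless of calendar day.
- A day with no visits has no windows: all of its EHR time is outside.

The implementation computes interval intersections with a cumulative
window-time function and is checked against a brute-force oracle that
assigns each whole second by point-in-interval testing, on randomized
instances, in both the unit tests and the acceptance script.

### Taxonomy

Action codes map to six clinical categories — reviewing data and reports,
creating/authenticating documentation, inbox/communication, entering/
authenticating orders, log-in, logout — and a fixed conceptual projection:
review → data review; documentation and orders → data entry; inbox → data
transmission; log-in/logout → other.  The projection is deliberately not
overridable per code, preserving comparability.  Unmapped codes are a
hard error by default (`unmapped_policy: uncategorized` downgrades them
to an explicitly reported bucket): misclassification by silence would
corrupt category shares.

## Reporting surfaces

The unit of all reporting is the **physician-workday**: a (physician,
date) with at least one retained action or at least one scheduled visit
(`workday_rule` can restrict to events-only or visits-only).
Per-physician averages weight workdays equally; cohort means and SDs are
taken across per-physician averages.  Rounding follows the conventional
printed style — hours to 2 decimals with integer column percents in the
category table, minutes to 1 decimal in the top-k table — with totals
computed on unrounded values and rounded last.  Top-k ties break by
frequency, then larger attributed minutes, then lexicographic code.
Administrative time is a configured fraction (default 11 %) of nominal
scheduled clinic hours divided by workdays.  High users are physicians
whose mean outside-hours per workday strictly exceeds 1.5 h.

## Crossed random-effects models

Daily (or ISO-weekly-summed) EHR hours — during, outside, or total — are
modelled with fixed effects for age, sex (indicator, male reference) and
clinical FTE, plus the same day's during-hours in minutes for the outside
model only, and *crossed* random intercepts for provider and calendar
day: every day is shared by many providers, so neither factor nests in
the other.  Estimation is REML via statsmodels MixedLM with the two
factors as variance components of a single grouping; one test
cross-checks coefficients and variance components against lme4's REML fit
of the identical model (agreement to ~4 decimals at test scale).

Model fitness is a variance partition: with T = var(x'β̂) + σ̂²_provider +
σ̂²_day + σ̂²_residual, the fixed R² is var(x'β̂)/T, the random R² is
(σ̂²_provider + σ̂²_day)/T, and the total is their sum — additive by
construction and invariant to affine rescaling of the outcome.  The
estimator is the standard variance-partition definition; it is a
documented default, not a claim about any particular prior analysis.
Numerical care: non-convergence triggers optimizer retries (lbfgs, then
powell) and is reported in a `converged` flag; a variance component at
the boundary 0, a single-provider design, or a constant outcome are
flagged `singular` with explanatory notes rather than raised.  A residual
normality check reports skewness, kurtosis and observed-vs-normal
quantiles and *recommends* a log1p transform when |skewness| > 1; nothing
is transformed silently.

## The synthetic cohort generator

The generator emulates the study conditions of a one-month primary-care
cohort: 62 rostered physicians — 56 eligible, plus 4 contingent, 1 with
zero clinical FTE and 1 who sees no patients, exercising every exclusion
rule — with demographics drawn at age 45.6 (SD 9.9, clipped 30–69), FTE
0.8 (SD 0.2), clinical FTE 0.5 (SD 0.2), 79 % female.  Per-physician mean
EHR time during clinic hours is Normal(4.4, 2.0) h clipped to 0.7–8.2;
outside-hours means are Normal(0.8, 0.8) floored at 0, which both matches
the reported 0–3.2 h range and leaves a point mass of physicians with no
outside use.  Day-level budgets add within-physician noise (SD 1.5 h
during, 0.5 h outside, the outside draw floored at 0 per physician-day);
these within-day SDs are the package's choice — only the between-physician
moments are stated conditions.

Attended weekdays (probability 0.9, giving ≈ 19 workdays/physician and
≈ 1070 physician-workdays over a September-2019-shaped month) carry two
half-day sessions of back-to-back 20-minute visits (08:00–11:00 and
13:00–16:00, i.e. 6 h of scheduled visits, whose ±30-min windows form two
merged intervals per day).  Event streams are built burst-wise: a day's
during-budget is split across the two windows and spent as bursts whose
log-normal inter-event gaps (mean 12.9 s — sized so a month yields
~1.5 M events — shape σ = 1) are renormalized to sum *exactly* to the
budget, with any renormalized gap above the cutoff split into sub-gaps;
bursts are separated by idle gaps of 16–25 minutes, which the idle filter
removes.  Outside-budgets go to an evening block (18:00–23:30), plus
occasional weekend activity (probability 0.05 per physician-weekend-day).
A budget that cannot fit its block is truncated with a warning and
tallied.  Because event times are integer seconds and every within-burst
gap survives the filter while every separation is removed, the *realized*
per-day budgets written to the ground-truth sidecar are recovered by the
pipeline exactly; recovery tests therefore assert equality to within one
second per day, and cohort-mean checks compare against the nominal
4.4/0.8 at two standard errors.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: actions arrive in clean bursts with stationary
gap distributions (real logs have device switches, overlapping sessions,
unscheduled walk-ins); category labels are drawn i.i.d. per event from
segment-specific time shares rather than from task sequences; there are
no DST transitions, vacations, or mid-month staffing changes; and visit
schedules are perfectly regular.  Clipping and budget truncation also
attenuate the realized between-physician SD (≈ 1.6 h vs the nominal 2.0
during clinic hours) and raise the realized outside mean slightly (the
floored draws are non-negative), which is why recovery is asserted
against realized ground truth and nominal values only at 2 SE.

A second generator, `simulate_model_data`, emits daily-summary-shaped
outcomes with known fixed coefficients and variance components
(provider SD 0.8, day SD 0.24 at the 56 × 19 design) for mixed-model
recovery tests.

## Problem sizes and determinism

Default test and acceptance runs use one full simulated month
(~1.5 M events, ≈ 35 s end to end including six model fits) plus
scaled-down cohorts (6 physicians × 2 weeks) for unit tests; the
brute-force interval oracle runs 1000 randomized instances; mixed-model
recovery averages 10 seeds.  All randomness flows from
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
generator output and pipeline results.

## Known limitations

Inter-event deltas bound, rather than measure, active use: the final
action before an idle gap contributes no time, and within-gap activity on
other systems is invisible.  Eligibility relies on roster flags (no
billing-volume computation).  Vendor-specific extraction, planned-versus-
actual schedule validation beyond optional reporting, and random slopes
or autocorrelated residual structures are out of scope.
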