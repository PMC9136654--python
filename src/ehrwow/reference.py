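"""Reference cohort surfaces from the source study, used as worked examples.

The original hospital audit logs are not public, so the study's
cohort-level tables cannot be recomputed from raw data.  What *can* be
checked is the arithmetic: every ratio, share and total that is fully
determined by the printed marginal values must come out of this package's
aggregation and rounding logic exactly.  The constants below are those
printed marginals; they are inputs to worked examples, never substitutes
for computation.
"""

from __future__ import annotations

import pandas as pd

#: Cohort construction: 62 candidate physicians, of whom 4 were excluded
#: for contingent employment, 1 for zero clinical FTE and 1 for seeing no
#: patients in the study month, leaving 56.
COHORT_CANDIDATES = 62
COHORT_EXCLUSIONS = {"contingent": 4, "zero_cfte": 1, "no_visits": 1}
COHORT_ELIGIBLE = 56

#: Study scale: audit-log data points and physician workdays.
N_EVENTS = 1_523_872
N_WORKDAYS = 1069

#: Hours per physician per workday (cohort mean, SD).
HOURS_DURING = (4.4, 2.0)
HOURS_OUTSIDE = (0.8, 0.8)

#: Vocabulary composition: 290 action codes by clinical category.
VOCAB_CODE_COUNTS = {
    "review": 161,
    "documentation": 64,
    "inbox": 34,
    "orders": 19,
    "login_logout": 12,
}

#: Category time table: hours per physician per workday by clinical
#: category and segment (the printed two-decimal cells).
CATEGORY_HOURS = pd.DataFrame(
    [
        ("review", 3.13, 0.59),
        ("documentation", 0.28, 0.05),
        ("inbox", 0.52, 0.08),
        ("orders", 0.12, 0.01),
        ("login", 0.03, 0.01),
        ("logout", 0.28, 0.02),
    ],
    columns=["category", "hours_during", "hours_outside"],
)

#: Printed segment totals (computed on unrounded data in the source, so
#: the during column's rounded cells sum to 4.36 while the printed total
#: is 4.35; the outside column is exactly determined by its cells).
CATEGORY_TOTALS = {"during": 4.35, "outside": 0.76, "total": 5.12}

#: Top-3 most frequent actions outside scheduled clinic hours per
#: clinical category: (category, action, frequency per physician-workday,
#: minutes per physician-workday).
TOP_ACTIONS_OUTSIDE = pd.DataFrame(
    [
        ("review", "patient_data_viewed", 28, 12.7),
        ("review", "encounter_data_viewed", 4, 3.5),
        ("review", "clinical_notes_viewed", 4, 3.2),
        ("documentation", "visit_template_used", 15, 1.1),
        ("documentation", "clinical_note_signed", 2, 0.4),
        ("documentation", "encounter_diagnoses_entered", 2, 0.3),
        ("inbox", "inbox_message_viewed", 8, 2.2),
        ("inbox", "inbox_message_created", 3, 0.7),
        ("inbox", "inbox_folder_loaded", 3, 0.7),
        ("orders", "outpatient_order_sets_used", 3, 0.2),
        ("orders", "order_list_changed", 1, 0.2),
        ("orders", "length_of_stay_entered", 1, 0.2),
    ],
    columns=["category", "action", "frequency", "minutes"],
)

#: Printed grand total of the top-3 table.
TOP_ACTIONS_TOTAL = {"frequency": 74, "minutes": 25.4}

#: High users of EHR outside clinic hours: physicians averaging >1.5 h
#: per workday (10 of 56), together 212 workdays at a 2.2 h mean.
HIGH_USERS = {"n": 10, "workdays": 212, "mean_outside_h": 2.2}

#: R² partitions (percent) of the crossed random-effects models.
R2_PARTITION = {
    "during": {"fixed": 10.0, "random": 41.4, "total": 51.4},
    "outside": {"fixed": 9.9, "random": 53.4, "total": 63.7},
    "total": {"fixed": 7.8, "random": 41.5, "total": 49.3},
}
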