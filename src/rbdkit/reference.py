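"""Published contingency tables from the reference depression cohort.

These are the reported cross-tabulations from the clinical cohort in
which the block-2 disengagement cutoff was first derived (195 depressed
participants, 40 healthy controls).  They serve as worked-example inputs:
the package's test statistics recomputed from these counts can be checked
against the values reported alongside them.

Each categorical table lists rows as categories and columns as
(disengaged, engaged) counts; the diagnosis table lists rows as
(depressed, control) and columns as (engaged, disengaged).
"""

from __future__ import annotations

#: engagement classification x diagnosis (rows: MDD, HC; cols: engaged, disengaged)
ENGAGEMENT_BY_DIAGNOSIS = [[137, 58], [35, 5]]

#: reported Pearson chi-square (no continuity correction) for the table above
REPORTED_CHI2_DIAGNOSIS = 5.03

N_MDD = 195
N_HC = 40
N_ENGAGED_MDD = 137
REPORTED_ENGAGED_PCT = 70.25

#: demographic feature -> (disengaged, engaged) counts per category
DEMOGRAPHIC_TABLES = {
    "sex": [[22, 44], [36, 93]],
    "race": [[39, 85], [15, 30], [4, 22]],
    "employment": [[11, 42], [14, 33], [33, 59]],
    "mde_length": [[19, 49], [14, 37], [25, 51]],
    "lifetime_mdes": [[15, 28], [11, 21], [28, 62]],
    "income": [[29, 51], [11, 35], [6, 28]],
    "marital_status": [[10, 30], [48, 105]],
    "comorbidities": [[20, 61], [8, 13], [9, 18], [16, 36]],
}

#: reported chi-square statistics for the tables above
REPORTED_CHI2 = {
    "sex": 0.62,
    "race": 3.02,
    "employment": 3.65,
    "mde_length": 0.60,
    "lifetime_mdes": 0.24,
    "income": 4.77,
    "marital_status": 0.61,
    "comorbidities": 1.88,
}
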