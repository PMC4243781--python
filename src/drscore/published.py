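"""Printed aggregates of the derivation cohort, as structured data.

The score was derived from a single-centre retrospective cohort of 75
patients (46 IISG, 29 IIDSG).  No per-patient data were deposited; what
survives are the printed aggregates below.  They drive the
reconstruction presets, the synthetic-generator calibration and the
reproduction report.

Two printed comparisons are documented here as *irreproducible* and are
excluded from any quantitative check:

* ``p = 0.1468`` for IISG non-remitters (10.2 ± 0.9, n 25) vs IIDSG
  remitters (9.7 ± 0.8, n 21): both t-test variants give ≈ 0.05 from
  the printed summaries.
* ``p = 0.07`` for the BMI ≥ 35 IISG subgroup: the subgroup n was not
  printed, so the test cannot be reformed.
* The obese/non-obese DRS rows (8.1 ± 0.8 vs 10.2 ± 0.9, 9.7 ± 0.8 vs
  12.0 ± 0.5) duplicate the remission/non-remission split exactly — a
  probable typesetting error — and are not used as targets.
"""

from __future__ import annotations

from .core import Procedure
from .stats import GroupSummary

__all__ = ["COHORTS", "IRREPRODUCIBLE", "TABLE2_MARGINALS"]

#: Printed per-procedure aggregates: cohort DRS summary, remission
#: counts, band rules and the remitter / non-remitter DRS summaries.
COHORTS = {
    Procedure.IISG: {
        "n": 46,
        "drs_mean": 9.2,
        "drs_sd": 1.4,
        "drs_range": (7, 13),
        "remitters": 21,
        "remission_rate_percent": 46,
        "all_remit_max_score": 8,     # every DRS 7-8 patient remitted
        "partial_score": 9,           # 35% of DRS 9 patients remitted
        "partial_percent": 35,
        "none_remit_min_score": 10,   # no remission at DRS >= 10
        "remitter_summary": {"n": 21, "mean": 8.1, "sd": 0.8},
        "non_remitter_summary": {"n": 25, "mean": 10.2, "sd": 0.9},
    },
    Procedure.IIDSG: {
        "n": 29,
        "drs_mean": 10.4,
        "drs_sd": 1.3,
        "drs_range": (8, 14),
        "remitters": 21,
        "remission_rate_percent": 72,
        "all_remit_max_score": 10,    # every DRS 8-10 patient remitted
        "partial_score": 11,          # 55% of DRS 11 patients remitted
        "partial_percent": 55,
        "none_remit_min_score": 12,   # no remission at DRS >= 12
        "remitter_summary": {"n": 21, "mean": 9.7, "sd": 0.8},
        "non_remitter_summary": {"n": 8, "mean": 12.0, "sd": 0.5},
    },
}

#: Between-procedure DRS comparison printed as p = 0.0004 (both t-test
#: variants reproduce it at four decimals from these summaries; ranges
#: are the observed score ranges).
BETWEEN_PROCEDURES = {
    Procedure.IISG: GroupSummary(n=46, mean=9.2, sd=1.4, min=7, max=13),
    Procedure.IIDSG: GroupSummary(n=29, mean=10.4, sd=1.3, min=8, max=14),
    "printed_p": 0.0004,
}

#: Printed values that cannot be recovered from the printed summaries.
IRREPRODUCIBLE = {
    "iisg_nonremit_vs_iidsg_remit_p": {
        "printed": 0.1468,
        "g1": GroupSummary(n=25, mean=10.2, sd=0.9, min=9, max=13),
        "g2": GroupSummary(n=21, mean=9.7, sd=0.8, min=8, max=11),
        "note": "both pooled and Welch give ≈0.05 from the printed summaries",
    },
    "bmi_ge_35_subgroup_p": {
        "printed": 0.07,
        "note": "subgroup n not printed; test cannot be reformed",
    },
    "table4_drs_rows": {
        "note": "duplicate the remission/non-remission split verbatim; probable typesetting error",
    },
}

#: Baseline clinical-profile marginals (mean, SD) per procedure, used to
#: parameterize the synthetic generator's raw-field distributions.
TABLE2_MARGINALS = {
    Procedure.IISG: {
        "age": (51.7, 13.3),
        "bmi": (23.4, 4.5),
        "dm_duration": (9.9, 4.8),
        "hba1c": (8.1, 0.59),
        "retinopathy_count": 21,
    },
    Procedure.IIDSG: {
        "age": (57.6, 11.5),
        "bmi": (25.6, 4.5),
        "dm_duration": (10.1, 5.0),
        "hba1c": (9.0, 0.78),
        "retinopathy_count": 13,
    },
}
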