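"""Published clinical surveillance tallies, used as worked-example inputs.

These are the site-level counts reported by a multi-year clinical
deployment of GDSA transit-image surveillance on a Halcyon linac
(retrospective cohort Nov 2017 - Dec 2020, prospective cohort from
Jan 2021) and the replan-rule contingency counts from its head-and-neck
case study.  The underlying patient images are not public; the tallies
serve as fixed inputs from which the package's arithmetic (cohort shares,
within-threshold rates, rule sensitivity/specificity) is recomputed.
"""

from __future__ import annotations

import pandas as pd

from .rules import ContingencyTable, sensitivity, specificity, truncate

#: Site-level retrospective tallies: patients, fractions, GDSA mean and SD
#: (percent), and the number of fractions with |GDSA| > 3 %.
SITE_TALLIES = pd.DataFrame(
    [
        ("abdomen_pelvis", 671, 17134, -0.02, 0.86, 126),
        ("head_and_neck", 390, 8909, 0.34, 1.15, 237),
        ("brain", 283, 5393, 0.07, 0.57, 8),
        ("chest_lungs", 254, 3833, 0.34, 1.46, 206),
        ("extremities", 35, 490, -0.26, 1.19, 20),
    ],
    columns=["site", "patients", "fractions", "mean", "sd", "n_exceeding_3pct"],
)

#: Cohort sizes and Type-B flag counts.
RETRO_PATIENTS = 1633
RETRO_TYPE_B_PATIENTS = 45
PROSPECTIVE_PATIENTS = 345
PROSPECTIVE_TYPE_B_PATIENTS = 13

#: Head-and-neck replan study contingency counts per rule variant
#: (tp, fn, fp, tn).
REPLAN_CONTINGENCIES: dict[str, ContingencyTable] = {
    "A": ContingencyTable(10, 38, 28, 105),
    "B": ContingencyTable(33, 19, 64, 66),
    "C": ContingencyTable(28, 24, 50, 80),
    "D": ContingencyTable(28, 24, 37, 93),
    "E": ContingencyTable(33, 19, 51, 79),
}


def total_fractions() -> int:
    """Total fractions across all treatment sites."""
    return int(SITE_TALLIES["fractions"].sum())


def site_share_percent(site: str) -> float:
    """One site's share of all fractions, rounded to the whole percent."""
    row = SITE_TALLIES.set_index("site").loc[site]
    return round(100.0 * row["fractions"] / total_fractions())


def within_threshold_percent() -> float:
    """Percent of fractions with |GDSA| <= 3 %, rounded to two decimals."""
    total = total_fractions()
    exceeding = int(SITE_TALLIES["n_exceeding_3pct"].sum())
    return round(100.0 * (total - exceeding) / total, 2)


def retro_type_b_rate_percent() -> float:
    """Retrospective Type-B patient rate (%), rounded to two decimals."""
    return round(100.0 * RETRO_TYPE_B_PATIENTS / RETRO_PATIENTS, 2)


def prospective_type_b_rate_percent() -> float:
    """Prospective Type-B patient rate (%), truncated to one decimal."""
    return truncate(100.0 * PROSPECTIVE_TYPE_B_PATIENTS / PROSPECTIVE_PATIENTS, 1)


def replan_rule_table() -> pd.DataFrame:
    """Sensitivity/specificity of the published replan-rule counts.

    Proportions carry the two-decimal truncation convention of
    :func:`epidwatch.rules.truncate`.
    """
    rows = []
    for name, ct in REPLAN_CONTINGENCIES.items():
        rows.append(
            {
                "rule": name,
                "tp": ct.tp,
                "fn": ct.fn,
                "fp": ct.fp,
                "tn": ct.tn,
                "sensitivity": truncate(sensitivity(ct)),
                "specificity": truncate(specificity(ct)),
            }
        )
    return pd.DataFrame(rows)
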