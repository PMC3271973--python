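"""Published cohort summary statistics used as default study conditions.

The original tumor RNA-Seq and serum cohorts are not publicly deposited;
what is published are their group-level summaries.  Those summaries are
recorded here as the default targets for the synthetic-data generator and
as inputs to the summary-only statistics (pooling, Welch-from-summaries).

All serum concentrations are IGFBP-4 in ng/ml; tumor values are RNA-Seq
coverage (RPKM).  ``GroupMoments`` rows are (n, mean, sd, low, high).
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = [
    "GroupMoments",
    "TUMOR_COVERAGE_GROUPS",
    "SERUM_GROUPS",
    "SERUM_CASE_GROUPS",
    "SERUM_CONTROL_GROUPS",
    "SCREEN_RETAINED",
    "SCREEN_DISQUALIFIED",
    "SURVEILLANCE_ABOVE_THRESHOLD",
    "SURVEILLANCE_GROUP_MEANS",
    "SURVEILLANCE_THRESHOLD_NG_ML",
    "CA125_CUTOFF_U_ML",
]


class GroupMoments(NamedTuple):
    n: int
    mean: float
    sd: float
    low: float
    high: float


#: Tumor RNA-Seq coverage of the candidate marker by disease group
#: (22 sequenced tumors: 2 borderline + 20 malignant).
TUMOR_COVERAGE_GROUPS: dict[str, GroupMoments] = {
    "Borderline": GroupMoments(2, 55.035, 14.425, 44.835, 65.235),
    "EarlyEOC": GroupMoments(5, 18.796, 16.450, 4.280, 37.895),
    "LateEOC": GroupMoments(11, 18.745, 14.412, 6.335, 60.005),
    "Disseminated": GroupMoments(2, 13.893, 10.737, 6.300, 21.485),
    "Recurrent": GroupMoments(2, 54.923, 17.999, 42.195, 67.650),
}

#: Serum marker concentration (ng/ml) of the validation cohort
#: (82 healthy controls + 78 cases).
SERUM_GROUPS: dict[str, GroupMoments] = {
    "Control": GroupMoments(82, 400.95, 470.8, 13.5, 1602.8),
    "Benign": GroupMoments(6, 394.60, 226.8, 83.2, 744.9),
    "EarlyEOC": GroupMoments(16, 1334.50, 1117.7, 20.9, 3323.3),
    "LateEOC": GroupMoments(40, 1305.40, 889.3, 41.4, 3360.1),
    "RecurrentEOC": GroupMoments(16, 1450.4, 1039.3, 65.3, 3583.2),
}

SERUM_CASE_GROUPS = ("EarlyEOC", "LateEOC", "RecurrentEOC")
SERUM_CONTROL_GROUPS = ("Control", "Benign")

#: Candidate-screen accounting: of the secreted, expressed working set,
#: how many survived (sd <= 75% of mean) vs were disqualified.
SCREEN_RETAINED = 541
SCREEN_DISQUALIFIED = 1169

#: Surveillance: serial readings strictly above the working threshold,
#: pooled within outcome group, as (above, total).
SURVEILLANCE_ABOVE_THRESHOLD: dict[str, tuple[int, int]] = {
    "AWD": (19, 33),
    "NED": (8, 35),
}

#: Pooled mean serial reading (ng/ml) per outcome group.
SURVEILLANCE_GROUP_MEANS: dict[str, float] = {"NED": 854.49, "AWD": 1206.53}

SURVEILLANCE_THRESHOLD_NG_ML = 1000.0
CA125_CUTOFF_U_ML = 35.0
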