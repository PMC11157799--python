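"""Published summary counts of the motivating hospital cohort.

The analysis was developed against a prospective two-hospital UK cohort of
adults admitted with acute lower respiratory tract disease (August 2020 -
July 2022) whose patient-level records are confidential. What the study
published are summary tables: counts of each characteristic split by
whether presenting symptoms met the syndromic LRTI case definition, plus
whole-cohort totals. Those printed counts are transcribed here; they serve
as calibration targets for the synthetic generator and as inputs for the
worked examples (every quantity derived from them is recomputed, never
hard-coded).

Each two-group entry is ``(not_meeting, meeting)`` with group totals
9,133 and 8,487 (17,620 confirmed LRTI cases overall).
"""

from __future__ import annotations

import pandas as pd

N_NOT_MEETING = 9_133
N_MEETING = 8_487
N_TOTAL = 17_620

#: Age-band counts by case-definition status.
AGE_BAND_COUNTS = {
    "18-24": (189, 254),
    "25-34": (506, 492),
    "35-44": (549, 691),
    "45-54": (681, 958),
    "55-64": (1_051, 1_327),
    "65-74": (1_486, 1_641),
    "75-84": (2_301, 1_851),
    "85+": (2_370, 1_273),
}

SARS_POSITIVE = (4_259, 3_051)
VACCINATED_YES = (5_524, 4_865)
VACCINATED_UNKNOWN = (683, 508)
CRB_COUNTS = {0: (5_853, 5_857), 1: (2_731, 2_269), 2: (501, 332), 3: (41, 25)}
CRB_UNKNOWN = (7, 4)
MALE_SEX = (4_601, 4_353)
CARE_HOME = (910, 482)
DEMENTIA = (1_285, 668)
FRAIL = (3_860, 2_785)
FRAIL_UNKNOWN = (2_145, 1_329)
CCI_COUNTS = {
    "0": (3_640, 3_449),
    "1-2": (3_707, 3_503),
    "3-4": (1_245, 1_137),
    ">4": (534, 394),
}
CCI_UNKNOWN = (7, 4)

#: Whole-cohort totals from the descriptive analysis.
N_SUSPECTED_ALRTD = 21_447
N_MEETING_RECRUITMENT_CRITERIA = 18_680
N_SARS_POSITIVE_TOTAL = 7_310
N_PNEUMONIA = 10_125
PNEUMONIA_RADIOLOGICAL_FRACTION = 0.904
N_CAP_SUBGROUP = 7_193


def age_counts_ge_65() -> tuple[int, int, int, int]:
    """Aggregate the age bands into the 2x2 of age >= 65 by definition status.

    Returns (meeting_ge65, not_meeting_ge65, meeting_lt65, not_meeting_lt65).
    """
    older = ("65-74", "75-84", "85+")
    meet_old = sum(AGE_BAND_COUNTS[b][1] for b in older)
    not_old = sum(AGE_BAND_COUNTS[b][0] for b in older)
    meet_young = N_MEETING - meet_old
    not_young = N_NOT_MEETING - not_old
    return meet_old, not_old, meet_young, not_young


def band_totals() -> dict[str, int]:
    return {b: sum(v) for b, v in AGE_BAND_COUNTS.items()}


def reference_table_frame() -> pd.DataFrame:
    """All two-group characteristic counts as a tidy frame (for display/tests)."""
    rows = []
    def add(char, level, pair):
        rows.append(dict(characteristic=char, level=str(level),
                         n_not_meeting=pair[0], n_meeting=pair[1]))
    for band, pair in AGE_BAND_COUNTS.items():
        add("age_group", band, pair)
    add("sars_cov2_positive", "yes", SARS_POSITIVE)
    add("sars_cov2_vaccinated", "yes", VACCINATED_YES)
    add("sars_cov2_vaccinated", "Unknown", VACCINATED_UNKNOWN)
    for level, pair in CRB_COUNTS.items():
        add("crb", level, pair)
    add("crb", "Unknown", CRB_UNKNOWN)
    add("male_sex", "yes", MALE_SEX)
    add("care_home", "yes", CARE_HOME)
    add("dementia", "yes", DEMENTIA)
    add("frail", "yes", FRAIL)
    add("frail", "Unknown", FRAIL_UNKNOWN)
    for level, pair in CCI_COUNTS.items():
        add("cci_cat", level, pair)
    add("cci_cat", "Unknown", CCI_UNKNOWN)
    return pd.DataFrame(rows)
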