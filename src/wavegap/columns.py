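"""Canonical column names and codings for the two-wave cohort tables.

Every module addresses variables through these constants so that the
generator, the reshaping utilities, the imputation engine and the analysis
models agree on one vocabulary.
"""

from __future__ import annotations

PID = "pid"
WAVE = "wave"
WAVES = ("W1", "W2")

# 9 depression items, 4-level codes 0..3 ("not at all" .. "nearly every day").
# Item 9 asks about thoughts of self-harm; item 4 asks about feeling tired.
PHQ_ITEMS = tuple(f"phq{i}" for i in range(1, 10))
IDEATION_ITEM = "phq9"
TIRED_ITEM = "phq4"

# 17 PTSD checklist items, 5-level codes 0..4 ("not at all" .. "extremely";
# "moderately" = 2).  DSM-IV symptom clusters: 5 intrusion, 7 avoidance,
# 5 hyperarousal, in instrument order.
PCL_ITEMS = tuple(f"pcl{i}" for i in range(1, 18))
PCL_INTRUSION = PCL_ITEMS[0:5]
PCL_AVOIDANCE = PCL_ITEMS[5:12]
PCL_HYPERAROUSAL = PCL_ITEMS[12:17]
PTSD_SCREEN = "ptsd_screen"

# 10 physical-functioning items, 3-level codes 0..2
# ("limited a lot" .. "not limited").
PF_ITEMS = tuple(f"pf{i}" for i in range(1, 11))

# 5 binary alcohol-problem items.
ALC_ITEMS = tuple(f"alc{i}" for i in range(1, 6))

SMOKING = "smoking"
SMOKING_LEVELS = ("never", "former", "current")

SLEEP_HOURS = "sleep_hours"
SLEEP_CAT = "sleep_cat"
SLEEP_LEVELS = ("le5", "6", "7-9", "ge10")
SLEEP_REF = "7-9"

SEX = "sex"
AGE_GROUP = "age_group"
RACE_ETH = "race_eth"
MARITAL = "marital"
EDUCATION = "education"
DEMOGRAPHICS = (SEX, AGE_GROUP, RACE_ETH, MARITAL, EDUCATION)

# Variables measured at every wave (everything except the fixed demographics).
WAVE_VARYING = (
    PHQ_ITEMS
    + PCL_ITEMS
    + (PTSD_SCREEN,)
    + PF_ITEMS
    + ALC_ITEMS
    + (SMOKING, SLEEP_HOURS, SLEEP_CAT)
)

ALL_VARIABLES = (PID, WAVE) + DEMOGRAPHICS + WAVE_VARYING


def categorize_sleep(hours):
    """Map nightly sleep hours to the four report categories.

    <=5 h, 6 h, 7-9 h (reference) and >=10 h, following the sleep-duration
    groupings used in the analysis models.
    """
    import numpy as np

    hours = np.asarray(hours, dtype=float)
    out = np.empty(hours.shape, dtype=object)
    out[hours <= 5.5] = SLEEP_LEVELS[0]
    out[(hours > 5.5) & (hours <= 6.5)] = SLEEP_LEVELS[1]
    out[(hours > 6.5) & (hours < 9.5)] = SLEEP_LEVELS[2]
    out[hours >= 9.5] = SLEEP_LEVELS[3]
    return out
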