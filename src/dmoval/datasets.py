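"""Bundled example data: an 11-participant hip-fracture validation cohort.

These small tables describe a reference cohort of community-dwelling older
adults monitored for 2.5 h in daily life between 32 and 390 days after
hip-fracture surgery.  They serve two purposes: deterministic fixtures for
the descriptive statistics and stratum bookkeeping, and the default
participant pool of the synthetic gait simulator.

``matched_bout_counts`` holds the per-participant true-positive walking-bout
counts by duration stratum (164 bouts total: 65 under 10 s, 60 between 10 and
30 s, 39 over 30 s) together with the number of bouts slower than 0.5 m/s.

The walking-aid flags are a synthetic assumption: the cohort is known to
contain two aid users (single cane or crutch), but not which participants;
here the two with the lowest SPPB scores are flagged.
"""
from __future__ import annotations

import pandas as pd

from .stride_store import ParticipantMeta

_COHORT_ROWS = [
    # pid,  days, age, height, weight, moca, pain, sppb, speed, sex,      fracture,       implant
    ("P01", 32, 71, 180, 78, 26, 5, 9, 0.79, "male", "cervical", "hemiprosthesis"),
    ("P02", 39, 76, 182, 85, 30, 3, 4, 0.39, "male", "cervical", "total_prosthesis"),
    ("P03", 60, 80, 169, 66, 27, 2, 3, 0.41, "female", "cervical", "total_prosthesis"),
    ("P04", 114, 84, 180, 69, 28, 4, 9, 0.89, "male", "cervical", "hemiprosthesis"),
    ("P05", 141, 79, 158, 54, 30, 0, 10, 0.80, "female", "trochanteric", "nail"),
    ("P06", 179, 83, 159, 44, 18, 30, 7, 0.83, "female", "trochanteric", "nail"),
    ("P07", 193, 87, 174, 71, 25, 19, 11, 1.34, "male", "trochanteric", "nail"),
    ("P08", 200, 72, 174, 95, 30, 4, 10, 1.05, "male", "cervical", "hemiprosthesis"),
    ("P09", 244, 71, 158, 53, 22, 52, 6, 0.75, "female", "trochanteric", "nail"),
    ("P10", 369, 83, 165, 66, 21, 2, 12, 1.08, "female", "trochanteric", "nail"),
    ("P11", 390, 90, 174, 96, 19, 1, 4, 0.62, "male", "cervical", "hemiprosthesis"),
]

#: Participants flagged as walking-aid users (synthetic assumption, see module docstring).
_AID_USERS = {"P03", "P11"}


def hip_fracture_cohort() -> list[ParticipantMeta]:
    """The 11-participant example cohort as validated metadata records."""
    metas = []
    for pid, days, age, height, weight, moca, pain, sppb, speed, sex, frac, implant in _COHORT_ROWS:
        metas.append(
            ParticipantMeta(
                participant_id=pid,
                days_since_surgery=days,
                age_y=age,
                height_cm=height,
                weight_kg=weight,
                moca=moca,
                pain_vas=pain,
                sppb=sppb,
                gait_speed_4mwt_mps=speed,
                sex=sex,
                walking_aid=pid in _AID_USERS,
                walking_aid_type="single cane or crutch" if pid in _AID_USERS else None,
                fracture_type=frac,
                implant=implant,
            )
        )
    return metas


_BOUT_COUNT_ROWS = [
    # pid,  all, gt10, 10to30, gt30, slow (<0.5 m/s by reference)
    ("P01", 14, 10, 5, 5, 2),
    ("P02", 1, 1, 0, 1, 0),
    ("P03", 12, 8, 4, 4, 10),
    ("P04", 21, 15, 8, 7, 3),
    ("P05", 27, 15, 13, 2, 2),
    ("P06", 12, 9, 7, 2, 3),
    ("P07", 14, 8, 5, 3, 2),
    ("P08", 17, 8, 1, 7, 3),
    ("P09", 35, 14, 11, 3, 8),
    ("P10", 1, 1, 1, 0, 0),
    ("P11", 10, 10, 5, 5, 3),
]


def matched_bout_counts() -> pd.DataFrame:
    """Per-participant true-positive bout counts by duration stratum."""
    return pd.DataFrame(
        _BOUT_COUNT_ROWS,
        columns=["participant_id", "all", "gt10", "10to30", "gt30", "slow_lt_0p5"],
    )
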