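"""Per-bout digital mobility outcomes (DMOs).

Six outcomes are computed for every walking bout, each as the average over
all member strides (not as totals divided by bout duration):

* stride duration (s): mean stride interval,
* cadence (steps/min): mean of 120 / stride duration — one stride spans two
  steps, so a d-second stride corresponds to 120/d steps per minute,
* stride length (m): mean of stride lengths,
* walking speed (m/s): mean of per-stride length / duration,
* number of steps: distinct initial-contact events in the bout,
* distance (m): average walking speed x bout duration.

Because the bout duration includes intra-bout pauses of up to 3 s while the
per-stride speed average does not, distance can exceed the sum of stride
lengths for bouts with pauses — an intentional property of the definition.

Bouts are binned by duration into <10 s, 10-30 s and >30 s; the ">10 s"
stratum used in reports is the union of the latter two.  Durations of exactly
10 s and exactly 30 s both fall in the 10-30 s bin.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .bout_builder import WalkingBout
from .stride_store import TIME_TOL_S, Foot


class DurationCategory(str, Enum):
    LT10 = "lt10"
    BETWEEN_10_30 = "10to30"
    GT30 = "gt30"


def duration_category(duration_s: float) -> DurationCategory:
    """Bin a bout duration; 10 s and 30 s belong to the 10-30 s bin."""
    if duration_s < 10.0:
        return DurationCategory.LT10
    if duration_s <= 30.0:
        return DurationCategory.BETWEEN_10_30
    return DurationCategory.GT30


@dataclass(frozen=True)
class BoutDMOs:
    """The six per-bout outcomes plus bout duration and its category.

    Spatial outcomes (walking speed, stride length, distance) are ``None``
    when any member stride lacks a length; ``has_spatial`` flags this rather
    than silently dropping the bout.
    """

    walking_speed_mps: float | None
    cadence_spm: float
    stride_length_m: float | None
    stride_duration_s: float
    n_steps: int
    distance_m: float | None
    duration_s: float
    duration_category: DurationCategory
    has_spatial: bool

    def value(self, dmo: str) -> float | None:
        return getattr(self, dmo)


#: The six DMO field names, in reporting order.
DMO_NAMES = [
    "walking_speed_mps",
    "cadence_spm",
    "stride_length_m",
    "n_steps",
    "stride_duration_s",
    "distance_m",
]

SPATIAL_DMOS = {"walking_speed_mps", "stride_length_m", "distance_m"}


def _count_initial_contacts(bout: WalkingBout) -> int:
    """Distinct IC events: each foot's contiguous chain of k strides has k+1 ICs.

    Chains are detected by per-foot adjacency (end of one stride equals the
    start of the next within the 1 ms time tolerance); a bout whose feet each
    form a single chain therefore has (total strides + 2) steps.
    """
    n_ics = 0
    for foot in (Foot.LEFT, Foot.RIGHT):
        chain_prev_end: float | None = None
        for s in bout.strides_for(foot):
            if chain_prev_end is None or abs(s.start_s - chain_prev_end) > TIME_TOL_S:
                n_ics += 2  # new chain: opening and closing IC
            else:
                n_ics += 1  # continues the chain: one new IC
            chain_prev_end = s.end_s
    return n_ics


def compute_bout_dmos(bout: WalkingBout) -> BoutDMOs:
    """Compute the six DMOs for a valid walking bout."""
    strides = bout.strides
    if not strides:
        raise ValueError("cannot compute DMOs for an empty bout")
    durations = [s.duration_s for s in strides]
    n = len(durations)
    stride_duration = sum(durations) / n
    cadence = sum(120.0 / d for d in durations) / n
    n_steps = _count_initial_contacts(bout)

    has_spatial = all(s.length_m is not None for s in strides)
    if has_spatial:
        lengths = [s.length_m for s in strides]
        stride_length = sum(lengths) / n
        walking_speed = sum(l / d for l, d in zip(lengths, durations)) / n
        distance = walking_speed * bout.duration_s
    else:
        stride_length = walking_speed = distance = None

    return BoutDMOs(
        walking_speed_mps=walking_speed,
        cadence_spm=cadence,
        stride_length_m=stride_length,
        stride_duration_s=stride_duration,
        n_steps=n_steps,
        distance_m=distance,
        duration_s=bout.duration_s,
        duration_category=duration_category(bout.duration_s),
        has_spatial=has_spatial,
    )


def dmos_to_frame(records) -> pd.DataFrame:
    """Flatten (participant_id, system, bout_id, BoutDMOs) tuples to a table."""
    rows = []
    for participant_id, system, bout_id, dmos in records:
        rows.append(
            {
                "participant_id": participant_id,
                "system": getattr(system, "value", system),
                "bout_id": bout_id,
                **{name: getattr(dmos, name) for name in DMO_NAMES},
                "duration_s": dmos.duration_s,
                "duration_category": dmos.duration_category.value,
            }
        )
    return pd.DataFrame(rows)
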