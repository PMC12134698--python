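"""Stride filtering and walking-bout assembly.

A walking bout (WB) is a continuous walking sequence comprising at least two
consecutive strides of both feet; bouts are separated by breaks of more than
3 seconds on the merged two-foot timeline.  Strides enter assembly only after
passing validity criteria: duration within [0.2, 3.0] s (inclusive) and, when
a length is present, length >= 0.15 m.

The gap between consecutive events on the merged timeline is the next
stride's start minus the latest end seen so far; strides of opposite feet
overlap in time, so overlapping or touching intervals have gap 0.  A break
splits a bout only when the gap is strictly greater than ``break_s`` —
intra-bout pauses of up to 3 s stay inside the bout, and the bout duration
(last stride end minus first stride start) includes them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .stride_store import Foot, SessionData, StrideRecord, System

#: Numerical slack for boundary comparisons on times built from floats.
_EPS = 1e-9


@dataclass(frozen=True)
class WBCriteria:
    """Stride validity and bout composition thresholds."""

    stride_min_s: float = 0.2
    stride_max_s: float = 3.0
    stride_min_len_m: float = 0.15
    break_s: float = 3.0
    min_strides_per_foot: int = 2

    def __post_init__(self) -> None:
        for name in ("stride_min_s", "stride_max_s", "stride_min_len_m", "break_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.stride_min_s < self.stride_max_s:
            raise ValueError("stride_min_s must be < stride_max_s")
        if self.min_strides_per_foot < 1:
            raise ValueError("min_strides_per_foot must be >= 1")


@dataclass(frozen=True)
class StrideRejection:
    stride: StrideRecord
    reason: str  # "duration" | "length"


def filter_strides(
    strides: Iterable[StrideRecord], criteria: WBCriteria = WBCriteria()
) -> tuple[list[StrideRecord], list[StrideRejection]]:
    """Apply stride validity criteria; never fails.

    Duration bounds are inclusive; the length test is skipped for strides
    without a length.  Returns (kept strides, rejection log).
    """
    kept: list[StrideRecord] = []
    rejected: list[StrideRejection] = []
    for s in strides:
        d = s.duration_s
        if d < criteria.stride_min_s - _EPS or d > criteria.stride_max_s + _EPS:
            rejected.append(StrideRejection(s, "duration"))
        elif s.length_m is not None and s.length_m < criteria.stride_min_len_m - _EPS:
            rejected.append(StrideRejection(s, "length"))
        else:
            kept.append(s)
    return kept, rejected


@dataclass(frozen=True)
class WalkingBout:
    """An assembled walking bout: member strides of both feet plus boundaries.

    ``start_s``/``end_s`` span from the first member stride's start to the
    last member stride's end; the duration includes intra-bout pauses.
    """

    participant_id: str
    system: System
    strides: tuple[StrideRecord, ...]

    def __post_init__(self) -> None:
        if not self.strides:
            raise ValueError("a walking bout must contain at least one stride")
        object.__setattr__(
            self, "strides", tuple(sorted(self.strides, key=StrideRecord.sort_key))
        )

    @property
    def start_s(self) -> float:
        return self.strides[0].start_s

    @property
    def end_s(self) -> float:
        return max(s.end_s for s in self.strides)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def strides_for(self, foot: Foot) -> tuple[StrideRecord, ...]:
        return tuple(s for s in self.strides if s.foot == foot)

    @property
    def n_left(self) -> int:
        return len(self.strides_for(Foot.LEFT))

    @property
    def n_right(self) -> int:
        return len(self.strides_for(Foot.RIGHT))


def _split_runs(
    strides: Sequence[StrideRecord], break_s: float
) -> list[list[StrideRecord]]:
    """Maximal runs in which every merged-timeline gap is <= break_s."""
    ordered = sorted(strides, key=StrideRecord.sort_key)
    runs: list[list[StrideRecord]] = []
    current: list[StrideRecord] = []
    latest_end = float("-inf")
    for s in ordered:
        if current and s.start_s - latest_end > break_s + _EPS:
            runs.append(current)
            current = []
        current.append(s)
        latest_end = max(latest_end, s.end_s)
    if current:
        runs.append(current)
    return runs


def assemble_bouts(
    strides: Iterable[StrideRecord],
    criteria: WBCriteria = WBCriteria(),
    participant_id: str = "",
    system: System = System.DEVICE,
) -> list[WalkingBout]:
    """Assemble filtered strides into walking bouts.

    Splits the merged two-foot stride timeline at gaps strictly greater than
    ``criteria.break_s`` and keeps maximal runs with at least
    ``min_strides_per_foot`` strides of each foot.  Bouts are non-overlapping
    and time-ordered.  Strides must already have passed
    :func:`filter_strides`; rejected strides are invisible here and may
    create gaps.
    """
    bouts: list[WalkingBout] = []
    for run in _split_runs(list(strides), criteria.break_s):
        n_left = sum(1 for s in run if s.foot == Foot.LEFT)
        n_right = sum(1 for s in run if s.foot == Foot.RIGHT)
        if n_left >= criteria.min_strides_per_foot and n_right >= criteria.min_strides_per_foot:
            bouts.append(
                WalkingBout(participant_id=participant_id, system=system, strides=tuple(run))
            )
    return bouts


def session_bouts(
    session: SessionData, criteria: WBCriteria = WBCriteria()
) -> tuple[list[WalkingBout], list[StrideRejection]]:
    """Filter then assemble one session; returns (bouts, rejection log)."""
    kept, rejected = filter_strides(session.strides, criteria)
    bouts = assemble_bouts(
        kept, criteria, participant_id=session.participant_id, system=session.system
    )
    return bouts, rejected


def bouts_to_frame(bouts: Iterable[WalkingBout]) -> pd.DataFrame:
    rows = []
    for i, b in enumerate(bouts):
        rows.append(
            {
                "participant_id": b.participant_id,
                "system": b.system.value,
                "bout_id": i,
                "start_s": b.start_s,
                "end_s": b.end_s,
                "duration_s": b.duration_s,
                "n_strides_left": b.n_left,
                "n_strides_right": b.n_right,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "system",
            "bout_id",
            "start_s",
            "end_s",
            "duration_s",
            "n_strides_left",
            "n_strides_right",
        ],
    )


def write_bout_table(bouts: Iterable[WalkingBout], path) -> None:
    bouts_to_frame(bouts).to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
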