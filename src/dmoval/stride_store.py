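"""Data model and delimited-text I/O for stride-level gait detections.

A *stride* is the interval between two consecutive initial contacts (ICs) of
the same foot.  Two measurement systems produce stride tables for the same
monitoring session: a single wearable ``device`` worn at the lower back and a
multisensor ``reference`` system.  Both sample at 100 Hz and are synchronized
to within +/-10 ms, so times are stored as decimal seconds from session start
at millisecond precision and compared with a 1 ms tolerance.

Stride intervals are closed at both ends: per-foot adjacency (the end of one
stride equals the start of the next) is legal and expected within continuous
walking.  Stride length may be absent (temporal-only records); downstream
stages must then skip spatial outcomes rather than invent them.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("dmoval")

#: Comparison tolerance for time stamps (systems are synchronized to +/-10 ms
#: and sample at 100 Hz; 1 ms resolves every legitimate distinction).
TIME_TOL_S = 1e-3


class Foot(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class System(str, Enum):
    DEVICE = "device"
    REFERENCE = "reference"


class FormatError(ValueError):
    """A stride or participant table violates the expected file format."""


class StrideValidationError(ValueError):
    """Rows parsed but violate stride invariants; carries offending row numbers."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


@dataclass(frozen=True)
class StrideRecord:
    """One detected stride of one foot.

    ``start_s`` is the initial contact opening the stride, ``end_s`` the next
    same-foot initial contact.  ``length_m`` may be ``None`` for temporal-only
    records.
    """

    foot: Foot
    start_s: float
    end_s: float
    length_m: float | None = None

    def __post_init__(self) -> None:
        if not (self.end_s > self.start_s):
            raise StrideValidationError(
                f"stride end ({self.end_s}) must exceed start ({self.start_s})"
            )
        if self.length_m is not None and not (self.length_m > 0):
            raise StrideValidationError(f"stride length must be > 0, got {self.length_m}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def sort_key(self) -> tuple[float, float]:
        return (self.start_s, self.end_s)


@dataclass(frozen=True)
class SessionData:
    """All strides of one participant from one system over one monitoring session."""

    participant_id: str
    system: System
    strides: tuple[StrideRecord, ...]
    session_span: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        strides = tuple(sorted(self.strides, key=StrideRecord.sort_key))
        object.__setattr__(self, "strides", strides)
        _check_per_foot_disjoint(strides)
        if self.session_span is not None:
            lo, hi = self.session_span
            for s in strides:
                if s.start_s < lo - TIME_TOL_S or s.end_s > hi + TIME_TOL_S:
                    raise StrideValidationError(
                        f"stride [{s.start_s}, {s.end_s}] outside session span [{lo}, {hi}]"
                    )

    @property
    def n_strides(self) -> int:
        return len(self.strides)


def _check_per_foot_disjoint(strides: Sequence[StrideRecord]) -> None:
    """Same-foot stride intervals may touch but not overlap."""
    last_end: dict[Foot, float] = {}
    bad: list[int] = []
    for i, s in enumerate(strides):
        prev = last_end.get(s.foot)
        if prev is not None and s.start_s < prev - TIME_TOL_S:
            bad.append(i)
        last_end[s.foot] = max(last_end.get(s.foot, -math.inf), s.end_s)
    if bad:
        raise StrideValidationError(
            f"overlapping same-foot stride intervals at sorted positions {bad}", rows=bad
        )


@dataclass(frozen=True)
class ParticipantMeta:
    """Clinical and demographic characteristics of one participant."""

    participant_id: str
    age_y: float | None = None
    sex: str | None = None
    height_cm: float | None = None
    weight_kg: float | None = None
    moca: float | None = None
    pain_vas: float | None = None
    sppb: float | None = None
    gait_speed_4mwt_mps: float | None = None
    days_since_surgery: int | None = None
    walking_aid: bool | None = None
    walking_aid_type: str | None = None
    fracture_type: str | None = None
    implant: str | None = None

    def __post_init__(self) -> None:
        def _range(name: str, value: float | None, lo: float, hi: float) -> None:
            if value is not None and not (lo <= value <= hi):
                raise StrideValidationError(
                    f"{name}={value} outside [{lo}, {hi}] for participant {self.participant_id}"
                )

        _range("sppb", self.sppb, 0, 12)
        _range("moca", self.moca, 0, 30)
        _range("pain_vas", self.pain_vas, 0, 100)
        if self.days_since_surgery is not None and self.days_since_surgery < 0:
            raise StrideValidationError(
                f"days_since_surgery must be >= 0, got {self.days_since_surgery}"
            )


# ---------------------------------------------------------------------------
# Stride table I/O (comma-separated, dot decimal, fixed column names)
# ---------------------------------------------------------------------------

STRIDE_COLUMNS = ["participant_id", "system", "foot", "start_s", "end_s", "length_m"]
_REQUIRED_STRIDE_COLUMNS = ["participant_id", "foot", "start_s", "end_s"]


def _parse_stride_frame(df: pd.DataFrame, path: str) -> list[tuple[str, StrideRecord]]:
    missing = [c for c in _REQUIRED_STRIDE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    has_length = "length_m" in df.columns

    records: list[tuple[str, StrideRecord]] = []
    bad_rows: list[tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        foot_raw = str(getattr(row, "foot")).strip().lower()
        try:
            foot = Foot(foot_raw)
        except ValueError:
            raise FormatError(f"{path}: unknown foot label {foot_raw!r} on line {idx}")
        length = getattr(row, "length_m") if has_length else None
        if length is not None and (isinstance(length, float) and math.isnan(length)):
            length = None
        try:
            rec = StrideRecord(
                foot=foot,
                start_s=float(getattr(row, "start_s")),
                end_s=float(getattr(row, "end_s")),
                length_m=None if length is None else float(length),
            )
        except (StrideValidationError, ValueError) as exc:
            bad_rows.append((idx, str(exc)))
            continue
        records.append((str(getattr(row, "participant_id")), rec))
    if bad_rows:
        detail = "; ".join(f"line {i}: {msg}" for i, msg in bad_rows)
        raise StrideValidationError(
            f"{path}: {len(bad_rows)} malformed stride row(s): {detail}",
            rows=[i for i, _ in bad_rows],
        )
    return records


def read_sessions(path, system_label: System | str) -> dict[str, SessionData]:
    """Read a stride CSV that may contain several participants.

    Returns a mapping participant_id -> validated :class:`SessionData`.
    """
    system = System(system_label)
    df = pd.read_csv(path, dtype={"participant_id": str})
    per_pid: dict[str, list[StrideRecord]] = {}
    for pid, rec in _parse_stride_frame(df, str(path)):
        per_pid.setdefault(pid, []).append(rec)
    return {
        pid: SessionData(participant_id=pid, system=system, strides=tuple(recs))
        for pid, recs in per_pid.items()
    }


def read_stride_table(path, system_label: System | str) -> SessionData:
    """Read a single-participant stride CSV into a validated SessionData."""
    sessions = read_sessions(path, system_label)
    if len(sessions) == 0:
        raise FormatError(f"{path}: no stride rows found")
    if len(sessions) > 1:
        raise FormatError(
            f"{path}: expected one participant, found {sorted(sessions)}; "
            "use read_sessions() for multi-participant files"
        )
    return next(iter(sessions.values()))


def sessions_to_frame(sessions: Iterable[SessionData]) -> pd.DataFrame:
    rows = []
    for sess in sessions:
        for s in sess.strides:
            rows.append(
                {
                    "participant_id": sess.participant_id,
                    "system": sess.system.value,
                    "foot": s.foot.value,
                    "start_s": s.start_s,
                    "end_s": s.end_s,
                    "length_m": s.length_m,
                }
            )
    return pd.DataFrame(rows, columns=STRIDE_COLUMNS)


def write_stride_table(session_or_sessions, path) -> None:
    """Write one or several sessions to a stride CSV.

    Round-trips through :func:`read_stride_table` up to 1e-6 s in the times.
    Absent lengths become empty cells, never zeros.
    """
    if isinstance(session_or_sessions, SessionData):
        sessions: list[SessionData] = [session_or_sessions]
    else:
        sessions = list(session_or_sessions)
    df = sessions_to_frame(sessions)
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


# ---------------------------------------------------------------------------
# Participant metadata I/O
# ---------------------------------------------------------------------------

PARTICIPANT_COLUMNS = [
    "participant_id",
    "days_since_surgery",
    "age_y",
    "sex",
    "height_cm",
    "weight_kg",
    "moca",
    "pain_vas",
    "sppb",
    "gait_speed_4mwt_mps",
    "walking_aid",
    "walking_aid_type",
    "fracture_type",
    "implant",
]

_FLOAT_META = {"age_y", "height_cm", "weight_kg", "moca", "pain_vas", "sppb", "gait_speed_4mwt_mps"}


def read_participant_table(path) -> list[ParticipantMeta]:
    """Read a participant metadata CSV; out-of-range SPPB/MoCA/VAS raise."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'participant_id'")
    if df.empty:
        logger.warning("participant table %s is empty", path)
        return []
    metas: list[ParticipantMeta] = []
    for row in df.to_dict(orient="records"):
        kwargs: dict = {"participant_id": str(row["participant_id"])}
        for col in _FLOAT_META:
            v = row.get(col)
            kwargs[col] = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        dss = row.get("days_since_surgery")
        kwargs["days_since_surgery"] = (
            None if dss is None or (isinstance(dss, float) and math.isnan(dss)) else int(dss)
        )
        for col in ("sex", "walking_aid_type", "fracture_type", "implant"):
            v = row.get(col)
            kwargs[col] = None if v is None or (isinstance(v, float) and math.isnan(v)) else str(v)
        aid = row.get("walking_aid")
        if aid is None or (isinstance(aid, float) and math.isnan(aid)):
            kwargs["walking_aid"] = None
        elif isinstance(aid, bool):
            kwargs["walking_aid"] = aid
        else:
            kwargs["walking_aid"] = str(aid).strip().lower() in {"true", "1", "yes", "y"}
        metas.append(ParticipantMeta(**kwargs))
    return metas


def write_participant_table(metas: Iterable[ParticipantMeta], path) -> None:
    rows = []
    for m in metas:
        rows.append({col: getattr(m, col) for col in PARTICIPANT_COLUMNS})
    pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS).to_csv(
        path, index=False, float_format="%.6f", lineterminator="\n"
    )
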