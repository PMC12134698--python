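"""Paired-sensor synthetic gait generator for free-living sessions.

Real raw sensor data for this validation problem are not publicly available,
so the simulator generates what the pipeline consumes: per-participant stride
streams for a nominal 2.5 h monitoring session, three ways — an error-free
*truth* stream, and *device* and *reference* streams derived from truth
through configurable error models.  The ground truth of every simulated bout
is recorded in a ledger so parameter-recovery tests can compare pipeline
output against analytically expected errors.

The generator emulates the statistical structure of real-world gait in older
adults after hip fracture:

* many short bouts — the default duration mixture targets ~40% under 10 s,
  ~37% between 10 and 30 s, ~24% over 30 s;
* group-dependent speeds — participants with SPPB < 8 draw bout speeds around
  0.59 m/s (SD 0.17), those with SPPB >= 8 around 0.70 m/s (SD 0.20),
  truncated above 0.2 m/s, with the group SD split between a per-participant
  baseline and within-participant bout-to-bout variation;
* cadence coupled to speed (cadence = 65 + 38 x speed steps/min, so 0.65 m/s
  walks at about 90 steps/min — a modelling choice, not a measured law);
* strictly alternating feet, mild step-time variability, optional intra-bout
  pauses of at most 3 s, and inter-bout gaps strictly greater than 3 s.

Error models transform a truth stream per stride in a fixed order:
miss -> timing jitter -> length perturbation -> spurious insertion ->
bout fragmentation.  Timing jitter perturbs initial-contact events (not
stride endpoints independently), preserving per-foot chain adjacency.

A single master seed derives per-participant and per-stream sub-seeds through
``numpy.random.SeedSequence`` spawning, so adding a participant never
perturbs the streams of existing ones.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bout_builder import WalkingBout, WBCriteria, assemble_bouts, session_bouts
from .datasets import hip_fracture_cohort
from .dmo_engine import compute_bout_dmos
from .stride_store import (
    Foot,
    ParticipantMeta,
    SessionData,
    StrideRecord,
    System,
    TIME_TOL_S,
    write_participant_table,
    write_stride_table,
)

LEDGER_COLUMNS = [
    "participant_id",
    "bout_id",
    "start_s",
    "end_s",
    "duration_s",
    "duration_category",
    "walking_speed_mps",
    "cadence_spm",
    "stride_length_m",
    "stride_duration_s",
    "n_steps",
    "distance_m",
]


@dataclass(frozen=True)
class ErrorModel:
    """Per-stream measurement error, applied stride-wise in a fixed order."""

    length_bias: float = 0.0  # multiplicative: observed = true * (1 + bias)
    length_noise_cv: float = 0.0  # multiplicative Gaussian noise CV
    timing_jitter_sd_s: float = 0.0  # per-IC Gaussian jitter
    miss_prob: float = 0.0  # per-stride miss probability
    spurious_rate_hz: float = 0.0  # Poisson rate of spurious strides per second
    fragmentation_prob: float = 0.0  # per-bout probability of a >3 s artificial gap

    def __post_init__(self) -> None:
        for name in ("miss_prob", "fragmentation_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("length_noise_cv", "timing_jitter_sd_s", "spurious_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def is_identity(self) -> bool:
        return self == ErrorModel()


#: Default device error: magnitudes chosen to emulate a lower-back wearable's
#: typical performance in slow, intermittent gait (about +10% stride-length
#: bias, substantial length noise, occasional missed strides and fragmented
#: bout detection).
DEVICE_ERROR_DEFAULT = ErrorModel(
    length_bias=0.10,
    length_noise_cv=0.15,
    timing_jitter_sd_s=0.01,
    miss_prob=0.04,
    spurious_rate_hz=0.0003,
    fragmentation_prob=0.12,
)

#: The reference system is treated as ground truth: error-free by default.
REFERENCE_ERROR_DEFAULT = ErrorModel()


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort."""

    participants: tuple[ParticipantMeta, ...] | None = None  # default: bundled 11-person cohort
    n_participants: int | None = None  # synthesize metadata when participants not given
    session_span_s: float = 9000.0  # 2.5 h
    bouts_per_session_mean: float = 15.0
    duration_shares: tuple[float, float, float] = (0.396, 0.366, 0.238)
    duration_short_range_s: tuple[float, float] = (5.5, 10.0)
    duration_mid_range_s: tuple[float, float] = (10.0, 30.0)
    duration_long_exp_mean_s: float = 40.0
    duration_long_max_s: float = 420.0
    speed_lower_mean_mps: float = 0.59
    speed_lower_sd_mps: float = 0.17
    speed_higher_mean_mps: float = 0.70
    speed_higher_sd_mps: float = 0.20
    speed_between_frac: float = 0.6  # share of group SD between participants
    speed_min_mps: float = 0.2
    speed_max_mps: float = 1.35
    cadence_intercept_spm: float = 65.0
    cadence_slope: float = 38.0
    cadence_noise_sd_spm: float = 4.0
    cadence_range_spm: tuple[float, float] = (55.0, 130.0)
    step_time_cv: float = 0.03
    pause_prob: float = 0.25
    pause_range_s: tuple[float, float] = (0.5, 2.8)
    inter_bout_gap_s: tuple[float, float] = (4.0, 40.0)
    sppb_threshold: int = 8
    device_error: ErrorModel = DEVICE_ERROR_DEFAULT
    reference_error: ErrorModel = REFERENCE_ERROR_DEFAULT

    def __post_init__(self) -> None:
        if abs(sum(self.duration_shares) - 1.0) > 1e-6:
            raise ValueError("duration_shares must sum to 1")
        if any(s < 0 for s in self.duration_shares):
            raise ValueError("duration_shares must be non-negative")
        if not 0.0 <= self.pause_prob <= 1.0:
            raise ValueError("pause_prob must be in [0, 1]")
        if self.pause_range_s[1] > 3.0:
            raise ValueError("intra-bout pauses must not exceed the 3 s break threshold")
        if self.inter_bout_gap_s[0] <= 3.0:
            raise ValueError("inter-bout gaps must be strictly greater than 3 s")


@dataclass
class SimulatedCohort:
    config: CohortConfig
    seed: int
    metas: list[ParticipantMeta]
    truth_sessions: dict[str, SessionData]
    device_sessions: dict[str, SessionData]
    reference_sessions: dict[str, SessionData]
    ledger: pd.DataFrame

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        order = [m.participant_id for m in self.metas]
        write_stride_table([self.device_sessions[p] for p in order], out / "device_strides.csv")
        write_stride_table([self.reference_sessions[p] for p in order], out / "reference_strides.csv")
        write_stride_table([self.truth_sessions[p] for p in order], out / "truth_strides.csv")
        write_participant_table(self.metas, out / "participants.csv")
        self.ledger.to_csv(out / "truth_ledger.csv", index=False, float_format="%.6f", lineterminator="\n")


# ---------------------------------------------------------------------------
# Truth-stream construction
# ---------------------------------------------------------------------------


def _ic_chain(
    t0: float, n_strides_per_foot: int, stride_dur_s: float, speed_mps: float,
    rng: np.random.Generator, step_cv: float,
) -> list[StrideRecord]:
    """One uninterrupted alternating-feet chain of strides starting at t0.

    Initial contacts alternate L,R,...; each foot's stride spans two of its
    consecutive ICs, so per-foot adjacency holds exactly within the chain.
    Stride length is speed x that stride's duration, so every stride walks at
    the bout speed.
    """
    m = n_strides_per_foot
    n_intervals = 2 * m + 1
    factors = 1.0 + step_cv * rng.standard_normal(n_intervals)
    np.clip(factors, 0.85, 1.15, out=factors)
    intervals = stride_dur_s / 2.0 * factors
    ics = t0 + np.concatenate([[0.0], np.cumsum(intervals)])
    strides: list[StrideRecord] = []
    for i in range(m):
        for foot, j in ((Foot.LEFT, 2 * i), (Foot.RIGHT, 2 * i + 1)):
            start, end = float(ics[j]), float(ics[j + 2])
            strides.append(
                StrideRecord(foot=foot, start_s=start, end_s=end, length_m=speed_mps * (end - start))
            )
    return strides


#: Safety margin (s) between a bout's nominal duration and its stratum
#: boundary, absorbing step-time noise so bouts stay in their sampled stratum.
_STRATUM_MARGIN_S = 0.35


def _strides_per_foot(walk_s: float, stride_dur: float) -> int:
    """m strides per foot give a nominal chain span of (2m+1) half-strides."""
    return int(round((2.0 * walk_s / stride_dur - 1.0) / 2.0))


def _build_bout(
    start_s: float, duration_target_s: float, bounds_s: tuple[float, float],
    speed_mps: float, cadence_spm: float,
    rng: np.random.Generator, config: CohortConfig,
) -> list[StrideRecord]:
    """Strides for one bout near the target duration, clamped to its stratum.

    The stride count is quantized to the stride-duration grid, so the number
    of strides per foot is clamped such that the nominal duration (including
    any intra-bout pause) respects the sampled duration stratum's bounds.
    """
    stride_dur = 120.0 / cadence_spm
    lo, hi = bounds_s
    pause = None
    if rng.random() < config.pause_prob:
        pause = float(rng.uniform(*config.pause_range_s))
        if _strides_per_foot(duration_target_s - pause, stride_dur) < 5:
            pause = None  # too few strides to split around a pause
    gap = pause or 0.0
    m = max(2, _strides_per_foot(duration_target_s - gap, stride_dur))
    walk_lo = max(lo + _STRATUM_MARGIN_S - gap, 0.0)
    m_min = max(2, math.ceil((2.0 * walk_lo / stride_dur - 1.0) / 2.0))
    if math.isfinite(hi):
        walk_hi = hi - _STRATUM_MARGIN_S - gap
        m_max = math.floor((2.0 * walk_hi / stride_dur - 1.0) / 2.0)
    else:
        m_max = 10**9
    if m_min <= m_max:
        m = min(max(m, m_min), m_max)
    else:  # stratum narrower than one stride: favor the upper bound
        m = max(2, m_max) if m_max >= 2 else m_min
    if pause is not None and m >= 5:
        m1, m2 = m // 2, m - m // 2
        chain_a = _ic_chain(start_s, m1, stride_dur, speed_mps, rng, config.step_time_cv)
        a_end = max(s.end_s for s in chain_a)
        chain_b = _ic_chain(a_end + pause, m2, stride_dur, speed_mps, rng, config.step_time_cv)
        return chain_a + chain_b
    return _ic_chain(start_s, m, stride_dur, speed_mps, rng, config.step_time_cv)


def _sample_duration(
    rng: np.random.Generator, config: CohortConfig
) -> tuple[float, tuple[float, float]]:
    """Sample (target duration, stratum bounds) from the configured mixture."""
    u = rng.random()
    s1, s2, _ = config.duration_shares
    if u < s1:
        return float(rng.uniform(*config.duration_short_range_s)), (0.0, 10.0)
    if u < s1 + s2:
        return float(rng.uniform(*config.duration_mid_range_s)), (10.0, 30.0)
    d = 30.0 + float(rng.exponential(config.duration_long_exp_mean_s))
    return min(d, config.duration_long_max_s), (30.0, float("inf"))


def _synthesize_metas(n: int, root: np.random.SeedSequence) -> list[ParticipantMeta]:
    """Minimal synthetic metadata when no explicit cohort is given.

    Each participant draws from an index-keyed stream so that growing the
    cohort leaves existing participants' metadata (and hence their gait
    streams) untouched.
    """
    metas = []
    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        metas.append(
            ParticipantMeta(
                participant_id=f"S{i + 1:03d}",
                days_since_surgery=int(rng.integers(30, 400)),
                age_y=float(rng.integers(65, 92)),
                sppb=float(rng.integers(3, 13)),
                sex="female" if rng.random() < 0.5 else "male",
                walking_aid=False,
            )
        )
    return metas


def _expected_bout_footprint_s(config: CohortConfig) -> float:
    s1, s2, s3 = config.duration_shares
    mean_dur = (
        s1 * np.mean(config.duration_short_range_s)
        + s2 * np.mean(config.duration_mid_range_s)
        + s3 * min(30.0 + config.duration_long_exp_mean_s, config.duration_long_max_s)
    )
    return float(mean_dur + np.mean(config.inter_bout_gap_s))


def simulate_cohort(config: CohortConfig = CohortConfig(), seed: int = 0) -> SimulatedCohort:
    """Generate truth, device and reference stride streams for a cohort.

    Raises before sampling when the expected walking plus gap time does not
    fit the session span.  Fixed seed and config give byte-identical output.
    """
    expected = config.bouts_per_session_mean * _expected_bout_footprint_s(config)
    if expected > 0.9 * config.session_span_s:
        raise ValueError(
            f"infeasible config: expected bout footprint {expected:.0f} s exceeds "
            f"90% of the session span {config.session_span_s:.0f} s"
        )

    root = np.random.SeedSequence(seed)
    if config.participants is not None:
        metas = list(config.participants)
    elif config.n_participants is not None:
        metas = _synthesize_metas(config.n_participants, root.spawn(1)[0])
    else:
        metas = hip_fracture_cohort()

    # Participant streams are seeded by index so the cohort can grow without
    # perturbing existing participants.
    children = root.spawn(len(metas) + 1)[1:]

    truth_sessions: dict[str, SessionData] = {}
    device_sessions: dict[str, SessionData] = {}
    reference_sessions: dict[str, SessionData] = {}
    ledger_rows: list[dict] = []

    for meta, child in zip(metas, children):
        truth_ss, dev_ss, ref_ss = child.spawn(3)
        rng = np.random.default_rng(truth_ss)

        sppb = meta.sppb if meta.sppb is not None else config.sppb_threshold
        if sppb < config.sppb_threshold:
            mean, sd = config.speed_lower_mean_mps, config.speed_lower_sd_mps
        else:
            mean, sd = config.speed_higher_mean_mps, config.speed_higher_sd_mps
        between_sd = config.speed_between_frac * sd
        within_sd = math.sqrt(max(sd**2 - between_sd**2, 0.0))
        baseline = float(rng.normal(mean, between_sd))

        n_bouts = max(2, int(rng.poisson(config.bouts_per_session_mean)))
        cursor = float(rng.uniform(*config.inter_bout_gap_s))
        strides: list[StrideRecord] = []
        bout_id = 0
        for _ in range(n_bouts):
            duration, bounds = _sample_duration(rng, config)
            if cursor + duration > config.session_span_s:
                break
            speed = float(np.clip(rng.normal(baseline, within_sd), config.speed_min_mps, config.speed_max_mps))
            cadence = float(
                np.clip(
                    config.cadence_intercept_spm + config.cadence_slope * speed
                    + rng.normal(0.0, config.cadence_noise_sd_spm),
                    *config.cadence_range_spm,
                )
            )
            bout_strides = _build_bout(cursor, duration, bounds, speed, cadence, rng, config)
            strides.extend(bout_strides)
            bout = WalkingBout(meta.participant_id, System.REFERENCE, tuple(bout_strides))
            dmos = compute_bout_dmos(bout)
            ledger_rows.append(
                {
                    "participant_id": meta.participant_id,
                    "bout_id": bout_id,
                    "start_s": bout.start_s,
                    "end_s": bout.end_s,
                    "duration_s": dmos.duration_s,
                    "duration_category": dmos.duration_category.value,
                    "walking_speed_mps": dmos.walking_speed_mps,
                    "cadence_spm": dmos.cadence_spm,
                    "stride_length_m": dmos.stride_length_m,
                    "stride_duration_s": dmos.stride_duration_s,
                    "n_steps": dmos.n_steps,
                    "distance_m": dmos.distance_m,
                }
            )
            bout_id += 1
            cursor = bout.end_s + float(rng.uniform(*config.inter_bout_gap_s))

        truth = SessionData(
            participant_id=meta.participant_id,
            system=System.REFERENCE,
            strides=tuple(strides),
            session_span=(0.0, config.session_span_s),
        )
        truth_sessions[meta.participant_id] = truth
        device_sessions[meta.participant_id] = replace(
            apply_error_model(truth, config.device_error, np.random.default_rng(dev_ss)),
            system=System.DEVICE,
        )
        reference_sessions[meta.participant_id] = apply_error_model(
            truth, config.reference_error, np.random.default_rng(ref_ss)
        )

    ledger = pd.DataFrame(ledger_rows, columns=LEDGER_COLUMNS)
    return SimulatedCohort(
        config=config,
        seed=seed,
        metas=metas,
        truth_sessions=truth_sessions,
        device_sessions=device_sessions,
        reference_sessions=reference_sessions,
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# Error-model application
# ---------------------------------------------------------------------------


def _foot_chains(strides: Sequence[StrideRecord], foot: Foot) -> list[list[StrideRecord]]:
    chains: list[list[StrideRecord]] = []
    for s in sorted((s for s in strides if s.foot == foot), key=StrideRecord.sort_key):
        if chains and abs(s.start_s - chains[-1][-1].end_s) <= TIME_TOL_S:
            chains[-1].append(s)
        else:
            chains.append([s])
    return chains


def _jitter_ics(strides: list[StrideRecord], sd: float, rng: np.random.Generator) -> list[StrideRecord]:
    """Jitter initial-contact events, preserving per-foot chain adjacency."""
    out: list[StrideRecord] = []
    for foot in (Foot.LEFT, Foot.RIGHT):
        for chain in _foot_chains(strides, foot):
            ics = [chain[0].start_s] + [s.end_s for s in chain]
            jittered = [t + float(rng.normal(0.0, sd)) for t in ics]
            for j in range(1, len(jittered)):  # keep ICs strictly increasing
                jittered[j] = max(jittered[j], jittered[j - 1] + 0.05)
            for s, start, end in zip(chain, jittered[:-1], jittered[1:]):
                out.append(StrideRecord(foot=foot, start_s=start, end_s=end, length_m=s.length_m))
    return sorted(out, key=StrideRecord.sort_key)


def _drop_same_foot_overlaps(strides: list[StrideRecord]) -> list[StrideRecord]:
    out: list[StrideRecord] = []
    last_end: dict[Foot, float] = {}
    for s in sorted(strides, key=StrideRecord.sort_key):
        prev = last_end.get(s.foot)
        if prev is not None and s.start_s < prev - TIME_TOL_S:
            continue
        out.append(s)
        last_end[s.foot] = s.end_s
    return out


def apply_error_model(
    session: SessionData, model: ErrorModel, rng: np.random.Generator | int
) -> SessionData:
    """Derive an observed stride stream from a truth stream.

    Transformations are applied in the fixed order miss -> jitter -> length
    perturbation -> spurious insertion -> fragmentation.  The identity model
    returns the session unchanged (bit-identical values).
    """
    if model.is_identity:
        return session
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    strides = list(session.strides)

    if model.miss_prob > 0:
        strides = [s for s in strides if rng.random() >= model.miss_prob]

    if model.timing_jitter_sd_s > 0 and strides:
        strides = _jitter_ics(strides, model.timing_jitter_sd_s, rng)

    if (model.length_bias != 0.0 or model.length_noise_cv > 0) and strides:
        perturbed = []
        for s in strides:
            if s.length_m is None:
                perturbed.append(s)
                continue
            factor = (1.0 + model.length_bias) * (1.0 + model.length_noise_cv * float(rng.standard_normal()))
            perturbed.append(replace(s, length_m=max(s.length_m * factor, 0.01)))
        strides = perturbed

    if model.spurious_rate_hz > 0:
        span = session.session_span or (
            (min(s.start_s for s in strides), max(s.end_s for s in strides)) if strides else (0.0, 1.0)
        )
        n_spurious = int(rng.poisson(model.spurious_rate_hz * (span[1] - span[0])))
        for _ in range(n_spurious):
            t = float(rng.uniform(span[0], max(span[1] - 2.0, span[0] + 1.0)))
            strides.append(
                StrideRecord(
                    foot=Foot.LEFT if rng.random() < 0.5 else Foot.RIGHT,
                    start_s=t,
                    end_s=t + float(rng.uniform(0.8, 1.6)),
                    length_m=float(rng.uniform(0.4, 1.0)),
                )
            )

    if model.fragmentation_prob > 0 and strides:
        kept = _drop_same_foot_overlaps(strides)
        bouts = assemble_bouts(kept, WBCriteria(), session.participant_id, session.system)
        windows: list[tuple[float, float]] = []
        for b in bouts:
            if b.duration_s > 9.0 and rng.random() < model.fragmentation_prob:
                t = float(rng.uniform(b.start_s + 2.0, b.end_s - 5.5))
                windows.append((t, t + 3.5))
        if windows:
            strides = [
                s
                for s in strides
                if not any(s.start_s < hi and s.end_s > lo for lo, hi in windows)
            ]

    strides = _drop_same_foot_overlaps(strides)
    return SessionData(
        participant_id=session.participant_id,
        system=session.system,
        strides=tuple(strides),
        session_span=session.session_span,
    )


# ---------------------------------------------------------------------------
# Parameter-recovery check
# ---------------------------------------------------------------------------


def expected_mre_pct(device: ErrorModel, reference: ErrorModel) -> dict[str, float]:
    """Analytic MRE expectations under the injected length-bias models.

    A multiplicative stride-length bias propagates one-to-one into stride
    length, walking speed and distance; cadence and stride duration are
    length-free and expect zero MRE (up to timing jitter).
    """
    rel = 100.0 * ((1.0 + device.length_bias) / (1.0 + reference.length_bias) - 1.0)
    return {
        "stride_length_m": rel,
        "walking_speed_mps": rel,
        "distance_m": rel,
        "cadence_spm": 0.0,
        "stride_duration_s": 0.0,
    }


def recovery_check(cohort: SimulatedCohort, report, tol_pct: float = 2.5) -> dict:
    """Compare pipeline MREs against the analytically expected values.

    ``report`` is a :class:`dmoval.strata_report.ValidationReport` produced
    from this cohort's device/reference sessions.  Raises when the report
    contains participants unknown to the cohort (mismatched runs).
    """
    cohort_ids = {m.participant_id for m in cohort.metas}
    report_ids = {p.participant_id for p in report.pairs}
    if not report_ids <= cohort_ids:
        raise ValueError(
            f"report/cohort mismatch: unknown participants {sorted(report_ids - cohort_ids)}"
        )
    expected = expected_mre_pct(cohort.config.device_error, cohort.config.reference_error)
    table = report.agreement_duration
    rows = []
    all_ok = True
    for dmo, exp in expected.items():
        obs_rows = table[(table["stratum"] == "all") & (table["dmo"] == dmo)]
        if obs_rows.empty:
            continue
        obs = float(obs_rows["mre_pct"].iloc[0])
        ok = abs(obs - exp) <= tol_pct
        all_ok = all_ok and ok
        rows.append({"dmo": dmo, "expected_mre_pct": exp, "observed_mre_pct": obs, "ok": ok})
    return {"rows": rows, "all_ok": all_ok, "tol_pct": tol_pct}
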