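"""Stratification and reporting: the end-to-end validation pipeline.

Matched pairs are stratified two ways:

* by walking-bout duration — all bouts, >10 s, 10-30 s, >30 s, keyed on the
  *reference* bout's duration by default (the reference system is treated as
  ground truth; device-keyed stratification is available for sensitivity
  analysis);
* by physical function — participants with SPPB < 8 (lower, impaired daily
  function) versus SPPB >= 8 (higher).

The report bundle mirrors the standard validation-paper layout: a bout-count
table by stratum x SPPB group x participant, per-DMO agreement tables per
duration stratum, walking-speed and distance agreement per SPPB group, and a
per-participant median/IQR table sorted by days since surgery, plus a JSON
run manifest.  Identical inputs and configuration yield a byte-identical
bundle.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import AgreementSummary, summarize_pairs
from .bout_builder import WBCriteria, session_bouts
from .bout_matcher import MatchedPair, MatchReport, match_bouts
from .dmo_engine import DMO_NAMES, duration_category
from .stride_store import ParticipantMeta, SessionData

logger = logging.getLogger("dmoval")

DURATION_STRATA = ["all", "gt10", "10to30", "gt30"]
SPPB_STRATA = ["lower", "higher"]
#: DMOs reported in the SPPB-stratified tables (most clinically relevant).
SPPB_DMOS = ["walking_speed_mps", "distance_m"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the validation pipeline."""

    criteria: WBCriteria = field(default_factory=WBCriteria)
    overlap_threshold: float = 0.80
    overlap_denominator: str = "both"  # both | reference_only | device_only
    match_method: str = "greedy"
    sppb_threshold: int = 8
    slow_speed_mps: float = 0.5
    duration_bounds_s: tuple[float, float] = (10.0, 30.0)
    quantile_method: str = "linear"
    stratify_by: str = "reference"  # reference | device

    def to_dict(self) -> dict:
        d = asdict(self)
        d["duration_bounds_s"] = list(self.duration_bounds_s)
        return d


# ---------------------------------------------------------------------------
# Grouping and stratification
# ---------------------------------------------------------------------------


def group_by_sppb(
    participants: Sequence[ParticipantMeta], threshold: int = 8
) -> tuple[list[ParticipantMeta], list[ParticipantMeta]]:
    """Split participants at the SPPB threshold: lower = score < threshold."""
    lower, higher = [], []
    for p in participants:
        if p.sppb is None:
            logger.warning("participant %s lacks an SPPB score; excluded from grouping", p.participant_id)
            continue
        (lower if p.sppb < threshold else higher).append(p)
    return lower, higher


def _stratum_duration(pair: MatchedPair, key: str) -> float:
    bout = pair.reference_bout if key == "reference" else pair.device_bout
    return bout.duration_s


def stratify(
    pairs: Sequence[MatchedPair], key: str = "reference"
) -> dict[str, list[MatchedPair]]:
    """Partition pairs into duration strata ('all' contains every pair).

    'gt10' is the union of '10to30' and 'gt30'; durations of exactly 10 s and
    30 s fall in '10to30'.
    """
    out: dict[str, list[MatchedPair]] = {s: [] for s in DURATION_STRATA}
    for p in pairs:
        out["all"].append(p)
        cat = duration_category(_stratum_duration(p, key)).value
        if cat != "lt10":
            out["gt10"].append(p)
            out[cat].append(p)
    return out


# ---------------------------------------------------------------------------
# Slow-bout counting and participant-level summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlowBoutSummary:
    per_participant: dict[str, int]
    per_participant_total: dict[str, int]
    n_slow: int
    n_total: int

    @property
    def pct(self) -> float:
        return 100.0 * self.n_slow / self.n_total if self.n_total else 0.0


def slow_bout_summary(
    counts: Mapping[str, int], totals: Mapping[str, int]
) -> SlowBoutSummary:
    """Aggregate per-participant slow-bout counts into the overall share."""
    return SlowBoutSummary(
        per_participant=dict(counts),
        per_participant_total=dict(totals),
        n_slow=int(sum(counts.values())),
        n_total=int(sum(totals.values())),
    )


def count_slow_bouts(
    pairs: Sequence[MatchedPair], speed_threshold: float = 0.5
) -> SlowBoutSummary:
    """Count matched bouts whose reference walking speed is below threshold."""
    counts: dict[str, int] = {}
    totals: dict[str, int] = {}
    for p in pairs:
        pid = p.participant_id
        totals[pid] = totals.get(pid, 0) + 1
        counts.setdefault(pid, 0)
        speed = p.reference_dmos.walking_speed_mps
        if speed is not None and speed < speed_threshold:
            counts[pid] += 1
    return slow_bout_summary(counts, totals)


def _median_iqr(values: Sequence[float], method: str = "linear") -> tuple[float, float, float]:
    v = np.asarray(values, dtype=float)
    med, q25, q75 = np.quantile(v, [0.5, 0.25, 0.75], method=method)
    return float(med), float(q25), float(q75)


def participant_medians(
    pairs: Sequence[MatchedPair],
    participant_id: str,
    stratum: str = "all",
    config: PipelineConfig = PipelineConfig(),
) -> dict | None:
    """Median (IQR) of walking speed and distance per system for one
    participant and duration stratum; ``None`` when no pairs exist."""
    strata = stratify(pairs, key=config.stratify_by)
    subset = [p for p in strata[stratum] if p.participant_id == participant_id]
    if not subset:
        return None
    row: dict = {"participant_id": participant_id, "stratum": stratum, "n": len(subset)}
    for dmo, label in (("walking_speed_mps", "speed"), ("distance_m", "distance")):
        for side, attr in (("ref", "reference_dmos"), ("dev", "device_dmos")):
            vals = [getattr(p, attr).value(dmo) for p in subset]
            vals = [v for v in vals if v is not None]
            if vals:
                med, q25, q75 = _median_iqr(vals, config.quantile_method)
            else:
                med = q25 = q75 = float("nan")
            row[f"{label}_{side}_median"] = med
            row[f"{label}_{side}_q25"] = q25
            row[f"{label}_{side}_q75"] = q75
    slow = count_slow_bouts(subset, config.slow_speed_mps)
    row["n_slow"] = slow.n_slow
    return row


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

_NUMERIC_META = [
    "days_since_surgery",
    "age_y",
    "height_cm",
    "weight_kg",
    "moca",
    "pain_vas",
    "sppb",
    "gait_speed_4mwt_mps",
]


def descriptive_stats(
    participants: Sequence[ParticipantMeta], quantile_method: str = "linear"
) -> pd.DataFrame:
    """Median (IQR) per numeric participant characteristic.

    For odd n the median is the exact middle order statistic.
    """
    if not participants:
        raise ValueError("descriptive_stats requires at least one participant")
    rows = []
    for name in _NUMERIC_META:
        vals = [getattr(p, name) for p in participants if getattr(p, name) is not None]
        if not vals:
            continue
        med, q25, q75 = _median_iqr(vals, quantile_method)
        rows.append({"characteristic": name, "n": len(vals), "median": med, "q25": q25, "q75": q75})
    return pd.DataFrame(rows, columns=["characteristic", "n", "median", "q25", "q75"])


# ---------------------------------------------------------------------------
# Full report bundle
# ---------------------------------------------------------------------------


def _summary_row(s: AgreementSummary, **extra) -> dict:
    row = dict(extra)
    row.update(
        {
            "dmo": s.dmo,
            "n": s.n,
            "ref_mean": s.ref_mean,
            "ref_q05": s.ref_q05,
            "ref_q95": s.ref_q95,
            "dev_mean": s.dev_mean,
            "dev_q05": s.dev_q05,
            "dev_q95": s.dev_q95,
            "me": s.me,
            "me_loa_low": s.me_loa[0] if s.me_loa else np.nan,
            "me_loa_high": s.me_loa[1] if s.me_loa else np.nan,
            "mre_pct": s.mre_pct,
            "mre_loa_low": s.mre_loa[0] if s.mre_loa else np.nan,
            "mre_loa_high": s.mre_loa[1] if s.mre_loa else np.nan,
            "mae": s.mae,
            "mae_q05": s.mae_q05,
            "mae_q95": s.mae_q95,
            "mare_pct": s.mare_pct,
            "mare_q05": s.mare_q05,
            "mare_q95": s.mare_q95,
            "icc": s.icc if s.icc is not None else np.nan,
            "icc_ci_low": s.icc_ci[0] if s.icc_ci else np.nan,
            "icc_ci_high": s.icc_ci[1] if s.icc_ci else np.nan,
            "icc_level": s.icc_level or "",
        }
    )
    return row


@dataclass
class ValidationReport:
    """All outputs of one validation run."""

    pairs: list[MatchedPair]
    match_reports: dict[str, MatchReport]
    bout_counts: pd.DataFrame
    agreement_duration: pd.DataFrame
    agreement_sppb: pd.DataFrame
    participant_table: pd.DataFrame
    descriptive: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(index=False, float_format="%.6f", lineterminator="\n")
        self.bout_counts.to_csv(out / "bout_counts.csv", **kw)
        self.agreement_duration.to_csv(out / "agreement_by_duration.csv", **kw)
        self.agreement_sppb.to_csv(out / "agreement_by_sppb.csv", **kw)
        self.participant_table.to_csv(out / "participant_summaries.csv", **kw)
        self.descriptive.to_csv(out / "participant_characteristics.csv", **kw)
        (out / "manifest.json").write_text(json.dumps(self.manifest, sort_keys=True, indent=2) + "\n")


def _check_ids(
    device_sessions: Mapping[str, SessionData],
    reference_sessions: Mapping[str, SessionData],
    metas: Sequence[ParticipantMeta],
) -> list[str]:
    dev, ref = set(device_sessions), set(reference_sessions)
    meta_ids = {m.participant_id for m in metas}
    orphans = sorted((dev ^ ref) | ((dev | ref) - meta_ids))
    if orphans:
        raise ValueError(
            f"inconsistent participant ids across inputs; orphans: {orphans}"
        )
    return sorted(dev)


def run_validation(
    device_sessions: Mapping[str, SessionData],
    reference_sessions: Mapping[str, SessionData],
    metas: Sequence[ParticipantMeta],
    config: PipelineConfig = PipelineConfig(),
    seed: int | None = None,
) -> ValidationReport:
    """Filter, assemble, match and summarize: the full validation pipeline."""
    pids = _check_ids(device_sessions, reference_sessions, metas)
    meta_by_id = {m.participant_id: m for m in metas}
    order = sorted(
        pids,
        key=lambda pid: (
            meta_by_id[pid].days_since_surgery
            if meta_by_id[pid].days_since_surgery is not None
            else 10**9,
            pid,
        ),
    )

    match_reports: dict[str, MatchReport] = {}
    all_pairs: list[MatchedPair] = []
    n_rejected = {"device": 0, "reference": 0}
    for pid in order:
        bouts_dev, rej_dev = session_bouts(device_sessions[pid], config.criteria)
        bouts_ref, rej_ref = session_bouts(reference_sessions[pid], config.criteria)
        n_rejected["device"] += len(rej_dev)
        n_rejected["reference"] += len(rej_ref)
        report = match_bouts(
            bouts_dev,
            bouts_ref,
            threshold=config.overlap_threshold,
            denominator=config.overlap_denominator,
            method=config.match_method,
            participant_id=pid,
        )
        match_reports[pid] = report
        all_pairs.extend(report.pairs)

    strata = stratify(all_pairs, key=config.stratify_by)
    lower, higher = group_by_sppb(list(meta_by_id.values()), config.sppb_threshold)
    lower_ids = {m.participant_id for m in lower}
    higher_ids = {m.participant_id for m in higher}
    no_sppb = [pid for pid in order if meta_by_id[pid].sppb is None]

    # --- bout counts by stratum x SPPB group x participant -----------------
    n_all = len(all_pairs)
    count_rows = []
    for stratum in DURATION_STRATA:
        subset = strata[stratum]
        row = {
            "stratum": stratum,
            "n": len(subset),
            "pct": 100.0 * len(subset) / n_all if n_all else 0.0,
            "n_lower_sppb": sum(1 for p in subset if p.participant_id in lower_ids),
            "n_higher_sppb": sum(1 for p in subset if p.participant_id in higher_ids),
        }
        for pid in order:
            row[f"n_{pid}"] = sum(1 for p in subset if p.participant_id == pid)
        count_rows.append(row)
    bout_counts = pd.DataFrame(count_rows)

    # --- agreement by duration stratum, all six DMOs -----------------------
    dur_rows = []
    for stratum in DURATION_STRATA:
        for dmo in DMO_NAMES:
            s = summarize_pairs(strata[stratum], dmo, config.quantile_method)
            if s is not None:
                dur_rows.append(_summary_row(s, stratum=stratum))
    agreement_duration = pd.DataFrame(dur_rows)

    # --- agreement by SPPB group x duration stratum, speed and distance ----
    sppb_rows = []
    for group_name, ids in (("lower", lower_ids), ("higher", higher_ids)):
        group_pairs = [p for p in all_pairs if p.participant_id in ids]
        group_strata = stratify(group_pairs, key=config.stratify_by)
        for stratum in DURATION_STRATA:
            for dmo in SPPB_DMOS:
                s = summarize_pairs(group_strata[stratum], dmo, config.quantile_method)
                if s is not None:
                    sppb_rows.append(_summary_row(s, sppb_group=group_name, stratum=stratum))
    agreement_sppb = pd.DataFrame(sppb_rows)

    # --- per-participant medians sorted by days since surgery --------------
    part_rows = []
    for pid in order:
        meta = meta_by_id[pid]
        for stratum in DURATION_STRATA:
            row = participant_medians(all_pairs, pid, stratum, config)
            if row is None:
                continue
            row["days_since_surgery"] = meta.days_since_surgery
            row["sppb"] = meta.sppb
            row["walking_aid"] = meta.walking_aid
            part_rows.append(row)
    participant_table = pd.DataFrame(part_rows)

    slow = count_slow_bouts(all_pairs, config.slow_speed_mps)
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "n_participants": len(order),
        "n_matched_pairs": n_all,
        "n_false_positives": sum(len(r.false_positives) for r in match_reports.values()),
        "n_false_negatives": sum(len(r.false_negatives) for r in match_reports.values()),
        "n_strides_rejected": n_rejected,
        "n_slow_bouts": slow.n_slow,
        "slow_bout_pct": slow.pct,
        "participants_without_sppb": no_sppb,
        "notes": [
            "bout durations of exactly 10 s and 30 s are assigned to the 10-30 s stratum",
            "ICC bands: exact 0.5 is moderate; exact 0.75 and 0.9 are good",
            "quantiles and IQRs use linear interpolation between order statistics"
            if config.quantile_method == "linear"
            else f"quantile method: {config.quantile_method}",
            f"duration strata keyed on the {config.stratify_by} bout's duration",
        ],
    }

    return ValidationReport(
        pairs=all_pairs,
        match_reports=match_reports,
        bout_counts=bout_counts,
        agreement_duration=agreement_duration,
        agreement_sppb=agreement_sppb,
        participant_table=participant_table,
        descriptive=descriptive_stats(metas, config.quantile_method),
        manifest=manifest,
    )
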