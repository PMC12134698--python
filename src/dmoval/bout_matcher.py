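"""True-positive matching of device bouts to reference bouts.

Two bouts detected by the two systems are treated as the same walking event
(a true positive) when their temporal overlap strictly exceeds 80% of bout
duration.  "Duration" is read symmetrically by default: the overlap must
exceed the threshold fraction of BOTH bouts' durations, which prevents one
long bout from absorbing fragments of the other system's detections.  The
denominator convention is configurable (``both`` | ``reference_only`` |
``device_only``).

Pairing is one-to-one and greedy in descending overlap, with deterministic
tie-breaks (earlier reference start, then earlier device start).  An optimal
assignment maximizing (pair count, total overlap) is available behind the
same interface for small instances and is used as the test oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .bout_builder import WalkingBout
from .dmo_engine import BoutDMOs, compute_bout_dmos


def overlap_seconds(bout_a: WalkingBout, bout_b: WalkingBout) -> float:
    """Length of the intersection of the two bout intervals, >= 0."""
    return max(0.0, min(bout_a.end_s, bout_b.end_s) - max(bout_a.start_s, bout_b.start_s))


@dataclass(frozen=True)
class MatchedPair:
    """One true-positive bout pair with both systems' outcomes."""

    participant_id: str
    device_bout: WalkingBout
    reference_bout: WalkingBout
    device_dmos: BoutDMOs
    reference_dmos: BoutDMOs
    overlap_s: float
    overlap_fraction_device: float
    overlap_fraction_reference: float


@dataclass(frozen=True)
class MatchReport:
    """Matched pairs plus unmatched bouts of either system.

    Unmatched device bouts are false positives, unmatched reference bouts
    false negatives; every input bout appears exactly once across the three
    lists.
    """

    pairs: tuple[MatchedPair, ...]
    false_positives: tuple[WalkingBout, ...]
    false_negatives: tuple[WalkingBout, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _eligible(
    device: WalkingBout, reference: WalkingBout, threshold: float, denominator: str
) -> tuple[bool, float, float, float]:
    ov = overlap_seconds(device, reference)
    if ov <= 0:
        return False, ov, 0.0, 0.0
    frac_dev = ov / device.duration_s
    frac_ref = ov / reference.duration_s
    if denominator == "both":
        ok = frac_dev > threshold and frac_ref > threshold
    elif denominator == "reference_only":
        ok = frac_ref > threshold
    elif denominator == "device_only":
        ok = frac_dev > threshold
    else:
        raise ValueError(f"unknown overlap denominator rule {denominator!r}")
    return ok, ov, frac_dev, frac_ref


def _greedy_select(candidates: list[tuple[float, float, float, int, int]]) -> list[tuple[int, int]]:
    """Pick pairs in descending overlap with deterministic tie-breaks."""
    order = sorted(candidates, key=lambda c: (-c[0], c[1], c[2]))
    used_dev: set[int] = set()
    used_ref: set[int] = set()
    chosen: list[tuple[int, int]] = []
    for ov, _ref_start, _dev_start, i, j in order:
        if i in used_dev or j in used_ref:
            continue
        used_dev.add(i)
        used_ref.add(j)
        chosen.append((i, j))
    return chosen


def _optimal_select(candidates: list[tuple[float, float, float, int, int]]) -> list[tuple[int, int]]:
    """Exhaustive matching maximizing (pair count, total overlap); small inputs only."""
    cands = sorted(candidates, key=lambda c: (-c[0], c[1], c[2]))
    best: tuple[int, float, list[tuple[int, int]]] = (0, 0.0, [])

    def recurse(k: int, used_dev: frozenset, used_ref: frozenset, count: int, total: float, taken: list) -> None:
        nonlocal best
        if count + (len(cands) - k) < best[0]:
            return
        if k == len(cands):
            if (count, total) > (best[0], best[1]):
                best = (count, total, list(taken))
            return
        ov, _, _, i, j = cands[k]
        if i not in used_dev and j not in used_ref:
            taken.append((i, j))
            recurse(k + 1, used_dev | {i}, used_ref | {j}, count + 1, total + ov, taken)
            taken.pop()
        recurse(k + 1, used_dev, used_ref, count, total, taken)

    recurse(0, frozenset(), frozenset(), 0, 0.0, [])
    return best[2]


def match_bouts(
    device_bouts: Sequence[WalkingBout],
    reference_bouts: Sequence[WalkingBout],
    threshold: float = 0.80,
    denominator: str = "both",
    method: str = "greedy",
    participant_id: str | None = None,
) -> MatchReport:
    """Pair device and reference bouts by the true-positive overlap rule.

    A candidate pair is eligible only when its overlap strictly exceeds
    ``threshold`` x duration under the chosen denominator rule.  Empty inputs
    yield an empty report.
    """
    candidates: list[tuple[float, float, float, int, int]] = []
    info: dict[tuple[int, int], tuple[float, float, float]] = {}
    for i, dev in enumerate(device_bouts):
        for j, ref in enumerate(reference_bouts):
            ok, ov, fd, fr = _eligible(dev, ref, threshold, denominator)
            if ok:
                candidates.append((ov, ref.start_s, dev.start_s, i, j))
                info[(i, j)] = (ov, fd, fr)

    if method == "greedy":
        chosen = _greedy_select(candidates)
    elif method == "optimal":
        if len(candidates) > 40:
            raise ValueError("optimal matching is intended for small instances only")
        chosen = _optimal_select(candidates)
    else:
        raise ValueError(f"unknown matching method {method!r}")

    pairs = []
    for i, j in sorted(chosen, key=lambda ij: reference_bouts[ij[1]].start_s):
        dev, ref = device_bouts[i], reference_bouts[j]
        ov, fd, fr = info[(i, j)]
        pairs.append(
            MatchedPair(
                participant_id=participant_id or ref.participant_id,
                device_bout=dev,
                reference_bout=ref,
                device_dmos=compute_bout_dmos(dev),
                reference_dmos=compute_bout_dmos(ref),
                overlap_s=ov,
                overlap_fraction_device=fd,
                overlap_fraction_reference=fr,
            )
        )
    matched_dev = {i for i, _ in chosen}
    matched_ref = {j for _, j in chosen}
    return MatchReport(
        pairs=tuple(pairs),
        false_positives=tuple(b for i, b in enumerate(device_bouts) if i not in matched_dev),
        false_negatives=tuple(b for j, b in enumerate(reference_bouts) if j not in matched_ref),
    )
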