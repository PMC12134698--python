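"""Shared builders for stride, bout and matched-pair fixtures."""
from __future__ import annotations

import numpy as np
import pytest

from dmoval import (
    Foot,
    MatchedPair,
    StrideRecord,
    System,
    WalkingBout,
    compute_bout_dmos,
)


def stride(foot, start, end, length=None):
    return StrideRecord(foot=Foot(foot), start_s=start, end_s=end, length_m=length)


def interval_bout(start, end, pid="P01", system=System.REFERENCE, speed=1.0):
    """A four-stride bout spanning exactly [start, end].

    Two adjacent left strides then two adjacent right strides cover the
    interval in quarters; stride length is speed x stride duration so every
    per-stride speed equals ``speed``.
    """
    q = (end - start) / 4.0
    strides = (
        stride("left", start, start + q, speed * q),
        stride("left", start + q, start + 2 * q, speed * q),
        stride("right", start + 2 * q, start + 3 * q, speed * q),
        stride("right", start + 3 * q, end, speed * q),
    )
    return WalkingBout(participant_id=pid, system=system, strides=strides)


def make_pair(pid="P01", start=0.0, duration=20.0, ref_speed=1.0, dev_speed=None,
              dev_duration=None):
    """A matched pair of co-located bouts with controllable speeds/durations."""
    ref = interval_bout(start, start + duration, pid, System.REFERENCE, ref_speed)
    dev = interval_bout(
        start, start + (dev_duration or duration), pid, System.DEVICE,
        ref_speed if dev_speed is None else dev_speed,
    )
    ov = min(ref.end_s, dev.end_s) - max(ref.start_s, dev.start_s)
    return MatchedPair(
        participant_id=pid,
        device_bout=dev,
        reference_bout=ref,
        device_dmos=compute_bout_dmos(dev),
        reference_dmos=compute_bout_dmos(ref),
        overlap_s=ov,
        overlap_fraction_device=ov / dev.duration_s,
        overlap_fraction_reference=ov / ref.duration_s,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)
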