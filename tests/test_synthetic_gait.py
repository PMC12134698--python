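"""Synthetic cohort generator: determinism, ground-truth consistency, error
model semantics, and distributional targets."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from dmoval import (
    CohortConfig,
    ErrorModel,
    apply_error_model,
    compute_bout_dmos,
    expected_mre_pct,
    match_bouts,
    recovery_check,
    run_validation,
    session_bouts,
    simulate_cohort,
)
from dmoval.bout_builder import assemble_bouts


def quick_config(**kwargs):
    defaults = dict(bouts_per_session_mean=8.0)
    defaults.update(kwargs)
    return CohortConfig(**defaults)


class TestDeterminism:
    def test_fixed_seed_reproduces_cohort_exactly(self):
        a = simulate_cohort(quick_config(), seed=42)
        b = simulate_cohort(quick_config(), seed=42)
        pd.testing.assert_frame_equal(a.ledger, b.ledger)
        for pid in a.truth_sessions:
            assert a.truth_sessions[pid].strides == b.truth_sessions[pid].strides
            assert a.device_sessions[pid].strides == b.device_sessions[pid].strides

    def test_different_seeds_differ(self):
        a = simulate_cohort(quick_config(), seed=1)
        b = simulate_cohort(quick_config(), seed=2)
        assert not a.ledger.equals(b.ledger)

    def test_adding_a_participant_never_perturbs_others(self):
        small = simulate_cohort(quick_config(n_participants=4), seed=5)
        big = simulate_cohort(quick_config(n_participants=6), seed=5)
        for pid in small.truth_sessions:
            assert small.truth_sessions[pid].strides == big.truth_sessions[pid].strides


class TestTruthConsistency:
    def test_zero_error_streams_equal_truth(self):
        cohort = simulate_cohort(quick_config(device_error=ErrorModel()), seed=3)
        for pid, truth in cohort.truth_sessions.items():
            assert cohort.device_sessions[pid].strides == truth.strides
            assert cohort.reference_sessions[pid].strides == truth.strides

    def test_reassembling_truth_reproduces_ledger_exactly(self):
        cohort = simulate_cohort(quick_config(), seed=13)
        for pid, truth in cohort.truth_sessions.items():
            bouts, rejected = session_bouts(truth)
            assert rejected == []
            expected = cohort.ledger[cohort.ledger["participant_id"] == pid]
            assert len(bouts) == len(expected)
            for bout, (_, row) in zip(bouts, expected.iterrows()):
                d = compute_bout_dmos(bout)
                assert d.walking_speed_mps == row["walking_speed_mps"]
                assert d.cadence_spm == row["cadence_spm"]
                assert d.stride_length_m == row["stride_length_m"]
                assert d.n_steps == row["n_steps"]
                assert d.distance_m == row["distance_m"]
                assert bout.start_s == row["start_s"]

    def test_infeasible_config_raises_before_sampling(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_cohort(CohortConfig(bouts_per_session_mean=500.0), seed=1)


class TestErrorModel:
    def truth(self, seed=17):
        cohort = simulate_cohort(quick_config(), seed=seed)
        pid = cohort.metas[0].participant_id
        return cohort.truth_sessions[pid]

    def test_identity_model_returns_stream_unchanged(self):
        truth = self.truth()
        observed = apply_error_model(truth, ErrorModel(), 0)
        assert observed.strides == truth.strides

    def test_miss_probability_one_empties_the_stream(self):
        observed = apply_error_model(self.truth(), ErrorModel(miss_prob=1.0), 0)
        assert observed.strides == ()

    def test_pure_length_bias_scales_every_length(self):
        truth = self.truth()
        observed = apply_error_model(truth, ErrorModel(length_bias=0.10), 0)
        assert len(observed.strides) == len(truth.strides)
        for obs, tru in zip(observed.strides, truth.strides):
            assert obs.start_s == tru.start_s and obs.end_s == tru.end_s
            assert obs.length_m == pytest.approx(1.1 * tru.length_m, rel=1e-12)

    def test_fragmentation_splits_long_bouts_downstream(self):
        truth = self.truth()
        truth_bouts, _ = session_bouts(truth)
        long_bouts = [b for b in truth_bouts if b.duration_s > 9.0]
        assert long_bouts, "fixture needs at least one long bout"
        observed = apply_error_model(truth, ErrorModel(fragmentation_prob=1.0), 0)
        observed_bouts, _ = session_bouts(observed)
        assert len(observed_bouts) > len(truth_bouts)

    def test_jitter_preserves_chain_adjacency_and_lengths(self):
        truth = self.truth()
        observed = apply_error_model(truth, ErrorModel(timing_jitter_sd_s=0.005), 0)
        assert len(observed.strides) == len(truth.strides)
        assert sorted(s.length_m for s in observed.strides) == sorted(
            s.length_m for s in truth.strides
        )
        # step counting depends on adjacency: jitter must not break chains
        for tb, ob in zip(session_bouts(truth)[0], session_bouts(observed)[0]):
            assert compute_bout_dmos(ob).n_steps == compute_bout_dmos(tb).n_steps

    def test_increasing_miss_never_increases_matched_bouts(self):
        cohort = simulate_cohort(quick_config(device_error=ErrorModel()), seed=23)
        pid = cohort.metas[0].participant_id
        truth = cohort.truth_sessions[pid]
        ref_bouts, _ = session_bouts(truth)
        counts = []
        for miss in (0.0, 0.2, 0.5, 0.9):
            observed = apply_error_model(truth, ErrorModel(miss_prob=miss), 99)
            dev_bouts, _ = session_bouts(observed)
            counts.append(match_bouts(dev_bouts, ref_bouts).n_pairs)
        assert counts == sorted(counts, reverse=True)


class TestDistributionalTargets:
    def test_duration_mixture_matches_configured_shares(self):
        cohort = simulate_cohort(CohortConfig(), seed=101)
        assert len(cohort.ledger) >= 150
        shares = cohort.ledger["duration_category"].value_counts(normalize=True) * 100
        assert shares["lt10"] == pytest.approx(39.6, abs=10)
        assert shares["10to30"] == pytest.approx(36.6, abs=10)
        assert shares["gt30"] == pytest.approx(23.8, abs=10)

    def test_group_speed_distributions(self):
        config = CohortConfig(n_participants=60, bouts_per_session_mean=12.0)
        cohort = simulate_cohort(config, seed=7)
        sppb = {m.participant_id: m.sppb for m in cohort.metas}
        ledger = cohort.ledger.assign(
            group=lambda d: d["participant_id"].map(lambda p: "lower" if sppb[p] < 8 else "higher")
        )
        by = ledger.groupby("group")["walking_speed_mps"]
        # wide tolerances: n=60 participants dominate the sampling error
        assert by.mean()["lower"] == pytest.approx(0.59, abs=0.05)
        assert by.mean()["higher"] == pytest.approx(0.70, abs=0.05)
        assert by.std()["lower"] == pytest.approx(0.17, abs=0.05)
        assert by.std()["higher"] == pytest.approx(0.20, abs=0.05)

    def test_intra_bout_pauses_stay_within_break_threshold(self):
        cohort = simulate_cohort(quick_config(pause_prob=1.0), seed=31)
        for truth in cohort.truth_sessions.values():
            bouts, _ = session_bouts(truth)
            # every generated bout survives assembly as one piece
            assert len(bouts) == len(
                cohort.ledger[cohort.ledger["participant_id"] == truth.participant_id]
            )


class TestRecovery:
    def test_expected_mre_propagates_length_bias(self):
        exp = expected_mre_pct(ErrorModel(length_bias=0.10), ErrorModel())
        assert exp["stride_length_m"] == pytest.approx(10.0)
        assert exp["walking_speed_mps"] == pytest.approx(10.0)
        assert exp["cadence_spm"] == 0.0

    def test_recovery_check_passes_on_pure_bias_run(self):
        config = quick_config(device_error=ErrorModel(length_bias=0.10))
        cohort = simulate_cohort(config, seed=19)
        report = run_validation(cohort.device_sessions, cohort.reference_sessions, cohort.metas)
        result = recovery_check(cohort, report, tol_pct=1.0)
        assert result["all_ok"], result["rows"]

    def test_mismatched_runs_are_a_hard_error(self):
        config = quick_config(device_error=ErrorModel(length_bias=0.10))
        cohort = simulate_cohort(config, seed=19)
        other = simulate_cohort(quick_config(n_participants=3), seed=19)
        report = run_validation(other.device_sessions, other.reference_sessions, other.metas)
        with pytest.raises(ValueError, match="mismatch"):
            recovery_check(cohort, report)
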