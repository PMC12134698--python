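"""Stratification, participant-level aggregation, descriptive statistics and
the end-to-end report bundle."""
import numpy as np
import pandas as pd
import pytest

from dmoval import (
    CohortConfig,
    ErrorModel,
    ParticipantMeta,
    PipelineConfig,
    count_slow_bouts,
    descriptive_stats,
    group_by_sppb,
    hip_fracture_cohort,
    matched_bout_counts,
    participant_medians,
    run_validation,
    simulate_cohort,
    slow_bout_summary,
    stratify,
)
from conftest import make_pair


class TestSppbGrouping:
    def test_example_cohort_splits_five_six(self):
        lower, higher = group_by_sppb(hip_fracture_cohort())
        assert len(lower) == 5 and len(higher) == 6
        assert all(m.sppb < 8 for m in lower)
        assert all(m.sppb >= 8 for m in higher)

    def test_score_exactly_eight_is_higher_function(self):
        lower, higher = group_by_sppb([ParticipantMeta("X", sppb=8)])
        assert not lower and len(higher) == 1

    def test_uniform_high_scores_leave_lower_group_empty(self):
        metas = [ParticipantMeta(f"P{i}", sppb=12) for i in range(4)]
        lower, higher = group_by_sppb(metas)
        assert lower == [] and len(higher) == 4

    def test_missing_sppb_excluded_with_warning(self, caplog):
        lower, higher = group_by_sppb(
            [ParticipantMeta("A", sppb=4), ParticipantMeta("B", sppb=None)]
        )
        assert len(lower) == 1 and not higher


class TestStratify:
    def test_reference_duration_keys_the_strata(self):
        pairs = [make_pair(duration=d) for d in (5.0, 15.0, 45.0)]
        strata = stratify(pairs)
        assert {k: len(v) for k, v in strata.items()} == {
            "all": 3, "gt10": 2, "10to30": 1, "gt30": 1,
        }

    def test_empty_pairs_give_empty_strata(self):
        assert all(len(v) == 0 for v in stratify([]).values())

    def test_device_keyed_stratification_uses_device_duration(self):
        pairs = [make_pair(duration=12.0, dev_duration=9.5)]
        assert len(stratify(pairs, key="reference")["gt10"]) == 1
        assert len(stratify(pairs, key="device")["gt10"]) == 0

    def test_partition_conservation(self, rng):
        pairs = [make_pair(duration=float(d)) for d in rng.uniform(4, 60, 40)]
        strata = stratify(pairs)
        assert len(strata["all"]) == 40
        assert len(strata["gt10"]) == len(strata["10to30"]) + len(strata["gt30"])
        in_bins = len(strata["10to30"]) + len(strata["gt30"]) + sum(
            1 for p in pairs if p.reference_bout.duration_s < 10
        )
        assert in_bins == 40


class TestBoutCountFixture:
    """Bookkeeping on the bundled 164-bout count table."""

    def test_stratum_shares(self):
        counts = matched_bout_counts()
        total = counts["all"].sum()
        assert total == 164
        shares = {
            c: round(100.0 * counts[c].sum() / total, 1) for c in ("gt10", "10to30", "gt30")
        }
        assert shares == {"gt10": 60.4, "10to30": 36.6, "gt30": 23.8}
        lt10 = total - counts["gt10"].sum()
        assert lt10 == 65
        assert round(100.0 * lt10 / total, 1) == 39.6

    def test_slow_bout_share(self):
        counts = matched_bout_counts()
        summary = slow_bout_summary(
            dict(zip(counts["participant_id"], counts["slow_lt_0p5"])),
            dict(zip(counts["participant_id"], counts["all"])),
        )
        assert summary.n_slow == 36 and summary.n_total == 164
        assert round(summary.pct, 1) == 22.0


class TestSlowBoutCounting:
    def test_counts_reference_speeds_below_threshold(self):
        pairs = [
            make_pair("A", start=0, ref_speed=0.4),
            make_pair("A", start=30, ref_speed=0.7),
            make_pair("B", start=0, ref_speed=0.45),
        ]
        summary = count_slow_bouts(pairs)
        assert summary.per_participant == {"A": 1, "B": 1}
        assert summary.pct == pytest.approx(100.0 * 2 / 3)

    def test_zero_threshold_counts_nothing(self):
        pairs = [make_pair(ref_speed=0.3)]
        assert count_slow_bouts(pairs, speed_threshold=0.0).n_slow == 0

    def test_all_below_threshold_is_100_percent(self):
        pairs = [make_pair(ref_speed=0.3), make_pair(start=40, ref_speed=0.2)]
        assert count_slow_bouts(pairs, speed_threshold=1.0).pct == 100.0


class TestParticipantMedians:
    def test_odd_count_median(self):
        pairs = [
            make_pair("A", start=t, duration=20.0, ref_speed=s)
            for t, s in ((0, 0.5), (40, 0.7), (80, 0.9))
        ]
        row = participant_medians(pairs, "A", "all")
        assert row["speed_ref_median"] == pytest.approx(0.7)
        assert row["n"] == 3

    def test_single_bout_degenerate_iqr(self):
        pairs = [make_pair("A", duration=20.0, ref_speed=0.8)]
        row = participant_medians(pairs, "A", "all")
        assert row["speed_ref_median"] == pytest.approx(0.8)
        assert row["speed_ref_q25"] == row["speed_ref_q75"] == pytest.approx(0.8)

    def test_no_pairs_is_absent_not_zero(self):
        assert participant_medians([], "A", "all") is None


class TestDescriptiveStats:
    def test_example_cohort_medians(self):
        table = descriptive_stats(hip_fracture_cohort()).set_index("characteristic")
        assert table.loc["days_since_surgery", "median"] == 179
        assert table.loc["age_y", "median"] == 80
        assert table.loc["moca", "median"] == 26
        assert table.loc["pain_vas", "median"] == 4
        assert table.loc["sppb", "median"] == 9
        assert table.loc["gait_speed_4mwt_mps", "median"] == pytest.approx(0.80)

    def test_gait_speed_iqr_by_linear_interpolation(self):
        table = descriptive_stats(hip_fracture_cohort()).set_index("characteristic")
        assert table.loc["gait_speed_4mwt_mps", "q25"] == pytest.approx(0.685)
        assert table.loc["gait_speed_4mwt_mps", "q75"] == pytest.approx(0.97)

    def test_single_participant(self):
        table = descriptive_stats([ParticipantMeta("A", sppb=7, age_y=80)])
        by = table.set_index("characteristic")
        assert by.loc["sppb", "median"] == 7
        assert by.loc["age_y", "q25"] == by.loc["age_y", "q75"] == 80


def small_cohort_config(**kwargs):
    defaults = dict(bouts_per_session_mean=8.0)
    defaults.update(kwargs)
    return CohortConfig(**defaults)


class TestEndToEndReport:
    def test_zero_error_run_is_perfect_in_every_stratum(self):
        config = small_cohort_config(device_error=ErrorModel())
        cohort = simulate_cohort(config, seed=7)
        report = run_validation(cohort.device_sessions, cohort.reference_sessions, cohort.metas)
        table = report.agreement_duration
        assert len(table) > 0
        assert (table["me"] == 0.0).all()
        assert (table["mre_pct"] == 0.0).all()
        assert (table["mae"] == 0.0).all()
        rich = table[table["n"] >= 2]
        assert (rich["icc"] == 1.0).all()
        assert report.manifest["n_false_positives"] == 0
        assert report.manifest["n_false_negatives"] == 0

    def test_report_bundle_is_deterministic(self, tmp_path):
        config = small_cohort_config()
        for d in ("run1", "run2"):
            cohort = simulate_cohort(config, seed=11)
            report = run_validation(
                cohort.device_sessions, cohort.reference_sessions, cohort.metas, seed=11
            )
            report.write(tmp_path / d)
        for name in (
            "bout_counts.csv",
            "agreement_by_duration.csv",
            "agreement_by_sppb.csv",
            "participant_summaries.csv",
            "participant_characteristics.csv",
            "manifest.json",
        ):
            a = (tmp_path / "run1" / name).read_bytes()
            b = (tmp_path / "run2" / name).read_bytes()
            assert a == b, f"{name} differs between identical runs"

    def test_bout_counts_sum_over_participants(self):
        cohort = simulate_cohort(small_cohort_config(), seed=3)
        report = run_validation(cohort.device_sessions, cohort.reference_sessions, cohort.metas)
        counts = report.bout_counts.set_index("stratum")
        pid_cols = [c for c in counts.columns if c.startswith("n_P")]
        for stratum in ("all", "gt10", "10to30", "gt30"):
            assert counts.loc[stratum, pid_cols].sum() == counts.loc[stratum, "n"]
        assert (
            counts.loc["gt10", "n"]
            == counts.loc["10to30", "n"] + counts.loc["gt30", "n"]
        )
        assert (
            counts.loc["all", "n_lower_sppb"] + counts.loc["all", "n_higher_sppb"]
            == counts.loc["all", "n"]
        )

    def test_orphan_participant_ids_are_a_hard_error(self):
        cohort = simulate_cohort(small_cohort_config(), seed=5)
        metas = cohort.metas[:-1]  # drop one participant's metadata
        with pytest.raises(ValueError, match="orphans"):
            run_validation(cohort.device_sessions, cohort.reference_sessions, metas)

    def test_sppb_table_covers_both_groups(self):
        cohort = simulate_cohort(small_cohort_config(), seed=9)
        report = run_validation(cohort.device_sessions, cohort.reference_sessions, cohort.metas)
        groups = set(report.agreement_sppb["sppb_group"])
        assert groups == {"lower", "higher"}
        assert set(report.agreement_sppb["dmo"]) == {"walking_speed_mps", "distance_m"}
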