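"""Flag rules, daily clinic statistics, and report bundles."""

import datetime as dt
import json

import numpy as np
import pytest

import epidwatch as ew

from conftest import make_record, make_trace


class TestTypeA:
    def test_single_large_deviation_flags_once(self):
        recs = make_trace([0.5, -11.2, 0.3])
        flags = ew.flag_type_a(recs)
        assert [f.trigger_fractions for f in flags] == [[2]]
        assert flags[0].kind == ew.TYPE_A
        assert flags[0].values_percent == [-11.2]

    def test_boundary_equality_does_not_flag(self):
        assert ew.flag_type_a(make_trace([9.9, -9.9, 10.0])) == []

    def test_quiet_course_never_flags(self):
        rng = np.random.default_rng(1)
        recs = make_trace(list(rng.uniform(-9.5, 9.5, 30)))
        assert ew.flag_type_a(recs) == []

    def test_omitted_records_ignored(self):
        recs = make_trace([0.0, 15.0])
        recs[1].status = "omitted"
        assert ew.flag_type_a(recs) == []


class TestTypeB:
    def test_three_consecutive_exceedances_flag_once(self):
        flags = ew.flag_type_b(make_trace([0.0, 3.5, 3.2, 3.1]))
        assert len(flags) == 1
        assert flags[0].trigger_fractions == [2, 3, 4]
        assert flags[0].kind == ew.TYPE_B

    def test_broken_run_does_not_flag(self):
        assert ew.flag_type_b(make_trace([0.0, 3.5, 2.9, 3.5, 3.5])) == []

    def test_mixed_signs_flag_under_magnitude_semantics(self):
        flags = ew.flag_type_b(make_trace([0.0, 3.5, -3.5, 3.5]))
        assert len(flags) == 1

    def test_same_sign_mode_requires_shared_sign(self):
        cfg = ew.FlagConfig(type_b_same_sign=True)
        assert ew.flag_type_b(make_trace([0.0, 3.5, -3.5, 3.5]), cfg) == []
        assert len(ew.flag_type_b(make_trace([0.0, 3.5, 3.5, 3.5]), cfg)) == 1

    def test_one_flag_per_maximal_run(self):
        flags = ew.flag_type_b(make_trace([0.0, 4.0, 4.0, 4.0, 4.0, 4.0]))
        assert len(flags) == 1
        assert flags[0].trigger_fractions == [2, 3, 4, 5, 6]

    def test_omitted_fraction_removed_before_consecutiveness(self):
        recs = make_trace([0.0, 3.5, 99.0, 3.4, 3.2])
        recs[2].status = "omitted"
        flags = ew.flag_type_b(recs)
        assert len(flags) == 1
        assert flags[0].trigger_fractions == [2, 4, 5]

    def test_subsumption_with_run_length_one(self):
        cfg = ew.FlagConfig(
            type_a_threshold_percent=3.0,
            type_b_threshold_percent=3.0,
            type_b_run_length=1,
        )
        rng = np.random.default_rng(7)
        recs = make_trace(list(rng.uniform(-6, 6, 40)))
        a_fractions = {
            fx for f in ew.flag_type_a(recs, cfg) for fx in f.trigger_fractions
        }
        b_fractions = {
            fx for f in ew.flag_type_b(recs, cfg) for fx in f.trigger_fractions
        }
        assert a_fractions == b_fractions


class TestThresholdMonotonicity:
    def test_type_a_count_never_decreases_when_threshold_drops(self):
        rng = np.random.default_rng(3)
        recs = make_trace(list(rng.uniform(-15, 15, 60)))
        counts = [
            len(ew.flag_type_a(recs, ew.FlagConfig(type_a_threshold_percent=t)))
            for t in (12.0, 10.0, 8.0, 5.0)
        ]
        assert counts == sorted(counts)

    def test_type_b_flagged_fraction_set_grows_when_threshold_drops(self):
        rng = np.random.default_rng(4)
        recs = make_trace(list(rng.uniform(-6, 6, 60)))
        sets = [
            {
                fx
                for f in ew.flag_type_b(
                    recs, ew.FlagConfig(type_b_threshold_percent=t)
                )
                for fx in f.trigger_fractions
            }
            for t in (4.0, 3.0, 2.0)
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_machine_count_never_decreases_when_threshold_drops(self):
        rng = np.random.default_rng(5)
        means = list(rng.uniform(-2, 2, 30))
        summaries = [
            ew.DailySummary(dt.date(2021, 3, 1) + dt.timedelta(days=i), 10, m, 0.5)
            for i, m in enumerate(means)
        ]
        counts = [
            len(
                ew.machine_output_flags(
                    summaries, ew.FlagConfig(machine_threshold_percent=t)
                )
            )
            for t in (2.0, 1.0, 0.5)
        ]
        assert counts == sorted(counts)


class TestDailySummary:
    def test_single_record_sd_undefined(self):
        s = ew.daily_summary([make_record(0.4, 1)])
        assert s.mean_percent == pytest.approx(0.4)
        assert s.sd_percent is None
        assert s.n_fractions == 1

    def test_sample_sd_with_two_records(self):
        day = dt.date(2021, 3, 1)
        recs = [
            make_record(1.0, 1, date=day, patient_id="A"),
            make_record(-1.0, 1, date=day, patient_id="B"),
        ]
        s = ew.daily_summary(recs)
        assert s.mean_percent == pytest.approx(0.0)
        assert s.sd_percent == pytest.approx(np.sqrt(2), abs=1e-5)

    def test_identical_records_sd_zero(self):
        day = dt.date(2021, 3, 1)
        recs = [make_record(2.0, 1, date=day, patient_id=f"P{i}") for i in range(20)]
        s = ew.daily_summary(recs)
        assert (s.mean_percent, s.sd_percent) == (2.0, 0.0)

    def test_no_complete_records_yields_no_summary(self):
        rec = make_record(5.0, 1, status="omitted")
        assert ew.daily_summary([rec]) is None


class TestMachineFlags:
    def _summaries(self, means, dates=None):
        if dates is None:
            dates = [dt.date(2021, 3, 1) + dt.timedelta(days=i) for i in range(len(means))]
        return [
            ew.DailySummary(d, 10, m, 0.5) for d, m in zip(dates, means)
        ]

    def test_large_day_to_day_change_flags(self):
        flags = ew.machine_output_flags(self._summaries([0.1, 1.3]))
        assert len(flags) == 1
        assert flags[0].kind == ew.MACHINE
        assert flags[0].values_percent == [0.1, 1.3]

    def test_subthreshold_changes_do_not_flag(self):
        assert ew.machine_output_flags(self._summaries([0.1, 0.9, 0.2])) == []

    def test_weekend_gap_days_are_adjacent(self):
        friday, monday = dt.date(2021, 3, 5), dt.date(2021, 3, 8)
        flags = ew.machine_output_flags(
            self._summaries([0.0, 1.6], dates=[friday, monday])
        )
        assert len(flags) == 1
        assert flags[0].trigger_dates == [friday, monday]

    def test_fewer_than_two_days_no_flags(self):
        assert ew.machine_output_flags(self._summaries([0.5])) == []


class TestBuildReport:
    def test_type_b_report_contents(self, tmp_path):
        recs = make_trace([0.0, 1.0, 3.5, 3.4, 3.2, 1.0, 0.5, 0.2, 0.1, 0.0])
        (flag,) = ew.flag_type_b(recs)
        bundle = ew.build_report(flag, recs, tmp_path, plot=False)
        summary = json.loads((bundle / "summary.json").read_text())
        assert summary["flag"]["kind"] == "TYPE_B"
        assert len(summary["flag"]["trigger_fractions"]) == 3
        assert len(summary["trace"]) == 10

    def test_machine_report_contains_both_means_and_difference(self, tmp_path):
        summaries = [
            ew.DailySummary(dt.date(2021, 3, 1), 10, 0.1, 0.5),
            ew.DailySummary(dt.date(2021, 3, 2), 10, 1.3, 0.5),
        ]
        (flag,) = ew.machine_output_flags(summaries)
        bundle = ew.build_report(flag, [], tmp_path, plot=False)
        summary = json.loads((bundle / "summary.json").read_text())
        assert summary["flag"]["values_percent"] == [0.1, 1.3]
        assert summary["daily_mean_difference_percent"] == pytest.approx(1.2)

    def test_report_is_byte_deterministic(self, tmp_path):
        recs = make_trace([0.0, -12.0, 0.1])
        (flag,) = ew.flag_type_a(recs)
        b1 = ew.build_report(flag, recs, tmp_path / "run1", plot=False)
        b2 = ew.build_report(flag, recs, tmp_path / "run2", plot=False)
        assert (b1 / "summary.json").read_bytes() == (b2 / "summary.json").read_bytes()

    def test_dangling_reference_rejected(self, tmp_path):
        recs = make_trace([0.0, -12.0, 0.1])
        (flag,) = ew.flag_type_a(recs)
        with pytest.raises(ew.ValidationError):
            ew.build_report(flag, recs[:1], tmp_path, plot=False)

    def test_plot_files_emitted(self, tmp_path, phantom, make_config):
        series, _ = ew.generate_course(
            phantom,
            make_config(n_fractions=4),
            [ew.ErrorInjection(ew.SPIKE, 3, 12.0)],
        )
        recs = ew.course_gdsa(series)
        (flag,) = ew.flag_type_a(recs)
        bundle = ew.build_report(flag, recs, tmp_path, images=series)
        assert (bundle / "trace.png").exists()
        assert any(p.name.startswith("diff_fx") for p in bundle.iterdir())
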