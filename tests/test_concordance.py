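import numpy as np
import pytest
from hypothesis import given, strategies as st

from cgmtrends import (
    DEXCOM_G5,
    PROFILES,
    ConcordanceRecord,
    DiaryRecord,
    GlucoseTrace,
    TherapyEvent,
    build_concordance,
    category_difference,
    contingency,
    parallel_sensor_agreement,
    stratify_by_visit,
    summarize,
    summary_from_counts,
    visit_label,
)
from cgmtrends.concordance import _round1
from cgmtrends.errors import ConfigurationError, ProfileMismatchError

from _bruteforce import analyze as bf_analyze, pair_agreement as bf_pairs, tabulate as bf_tabulate
from conftest import study_to_plain


def diary_rec(code, t=100.0, pid="P01", sensor="P01-DG5-1", system="DG5", visit=1):
    return DiaryRecord(
        participant_id=pid, system=system, sensor_id=sensor, time=t,
        recorded=PROFILES[system].category(code), visit=visit,
    )


def simple_trace(sensor_id="P01-DG5-1"):
    # Rises 36 mg/dL over [100, 130]: the +1.2 mg/(dL.min) worked example.
    return GlucoseTrace(
        sensor_id=sensor_id,
        times=np.array([70.0, 100.0, 130.0, 160.0]),
        values=np.array([120.0, 120.0, 156.0, 156.0]),
    )


class TestBuildConcordance:
    def test_worked_example_pairing(self):
        records, excl = build_concordance(
            [diary_rec(+1)], {"P01-DG5-1": simple_trace()}, [], DEXCOM_G5, max_gap=40,
        )
        assert not excl
        (rec,) = records
        assert rec.calculated.code == 1
        assert rec.diff == 0
        assert rec.in_window is False

    def test_out_of_range_record_excluded_and_logged(self):
        records, excl = build_concordance(
            [diary_rec(+1, t=150.0)], {"P01-DG5-1": simple_trace()}, [], DEXCOM_G5, max_gap=40,
        )
        assert records == []
        assert [e.reason for e in excl] == ["out-of-range"]

    def test_gap_record_excluded(self):
        tr = GlucoseTrace(
            "P01-DG5-1", np.array([0.0, 100.0, 300.0]), np.array([100.0, 120.0, 150.0])
        )
        _, excl = build_concordance(
            [diary_rec(0, t=100.0)], {"P01-DG5-1": tr}, [], DEXCOM_G5, max_gap=12.5,
        )
        assert [e.reason for e in excl] == ["gap"]

    def test_unknown_sensor_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="P01-DG5-1"):
            build_concordance([diary_rec(0)], {}, [], DEXCOM_G5)

    def test_empty_diary_yields_empty_result(self):
        records, excl = build_concordance([], {}, [], DEXCOM_G5)
        assert records == [] and excl == []

    def test_event_window_flag_set_from_own_participant_events(self):
        events = [
            TherapyEvent("P01", 110.0, "CHO", 30.0),       # t=100 inside (-30, +120)
            TherapyEvent("P02", 100.0, "insulin_bolus"),   # other participant
        ]
        records, _ = build_concordance(
            [diary_rec(+1)], {"P01-DG5-1": simple_trace()}, events, DEXCOM_G5, max_gap=40,
        )
        assert records[0].in_window is True
        records, _ = build_concordance(
            [diary_rec(+1)], {"P01-DG5-1": simple_trace()},
            [TherapyEvent("P02", 100.0, "CHO")], DEXCOM_G5, max_gap=40,
        )
        assert records[0].in_window is False

    def test_bg_reference_uses_participant_trace(self):
        bg = {"P01": simple_trace(sensor_id="P01-BG")}
        records, _ = build_concordance(
            [diary_rec(+1)], bg, [], DEXCOM_G5, reference="BG", max_gap=40,
        )
        assert records[0].calculated.code == 1
        assert records[0].reference == "BG"


class TestContingency:
    def test_empty_is_all_zero(self):
        mat = contingency([], DEXCOM_G5)
        assert mat.shape == (7, 7)
        assert mat.to_numpy().sum() == 0

    def test_repeated_cell(self):
        records, _ = build_concordance(
            [diary_rec(+1)] * 3, {"P01-DG5-1": simple_trace()}, [], DEXCOM_G5, max_gap=40,
        )
        mat = contingency(records, DEXCOM_G5)
        assert mat.loc[1, 1] == 3
        assert mat.to_numpy().sum() == 3

    def test_marginals_and_diagonal(self, small_study):
        records, _ = build_concordance(
            small_study.diary_for("DG5"), small_study.traces, small_study.events, DEXCOM_G5
        )
        mat = contingency(records, DEXCOM_G5)
        assert mat.to_numpy().sum() == len(records)
        assert np.trace(mat.to_numpy()) == sum(1 for r in records if r.diff == 0)
        # Row marginals count the recorded categories.
        for code in range(-3, 4):
            assert mat.loc[code].sum() == sum(
                1 for r in records if r.diary.recorded.code == code
            )

    def test_mixed_profiles_rejected(self, small_study):
        records, _ = build_concordance(
            small_study.diary_for("FL"), small_study.traces, [], PROFILES["FL"]
        )
        with pytest.raises(ProfileMismatchError):
            contingency(records[:5], DEXCOM_G5)


class TestSummarize:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((1206, 629, 308), (56.3, 29.4, 14.4)),   # visit 1, 5-min system
            ((1404, 585, 216), (63.7, 26.5, 9.8)),    # visit 2, 5-min system
            ((1123, 675, 288), (53.8, 32.4, 13.8)),   # visit 1, flash system
            ((1053, 544, 185), (59.1, 30.5, 10.4)),   # visit 3, flash system
        ],
    )
    def test_published_count_arithmetic(self, counts, expected):
        s = summary_from_counts(*counts)
        assert (s.pct_match, s.pct_off1, s.pct_off2plus) == expected
        assert s.n == sum(counts)

    def test_all_matching(self):
        s = summary_from_counts(25, 0, 0)
        assert (s.pct_match, s.pct_off1, s.pct_off2plus) == (100.0, 0.0, 0.0)

    def test_empty_flags_absent_percentages(self):
        s = summarize([])
        assert s.n == 0
        assert s.pct_match is None and s.participant_mean_match is None

    def test_round_half_up_display_convention(self):
        assert _round1(56.25) == 56.3
        assert _round1(9.74999) == 9.7
        assert _round1(-0.05) == -0.1  # away from zero

    def test_participant_mean_and_sample_sd(self):
        # P01: 2 of 4 match (50%); P02: 3 of 4 match (75%).
        def rec(pid, diff):
            d = diary_rec(0, pid=pid, sensor=f"{pid}-DG5-1")
            calc = DEXCOM_G5.category(diff)
            return ConcordanceRecord(d, calc, category_difference(d.recorded, calc), False, "TG")

        records = [rec("P01", d) for d in (0, 0, 1, 2)] + [rec("P02", d) for d in (0, 0, 0, 1)]
        s = summarize(records)
        assert s.participant_mean_match == pytest.approx(62.5)
        assert s.participant_sd_match == pytest.approx(np.std([50.0, 75.0], ddof=1))

    @given(
        counts=st.tuples(
            st.integers(0, 4000), st.integers(0, 4000), st.integers(0, 4000)
        ).filter(lambda c: sum(c) > 0)
    )
    def test_percentage_conservation(self, counts):
        s = summary_from_counts(*counts)
        assert abs(s.pct_match + s.pct_off1 + s.pct_off2plus - 100.0) <= 0.1 + 1e-9

    def test_noiseless_self_consistency(self, small_study):
        """Replacing every recorded arrow by its own calculated category
        must produce a perfect match."""
        records, _ = build_concordance(
            small_study.diary_for("DG5"), small_study.traces, [], DEXCOM_G5
        )
        forced = [
            ConcordanceRecord(
                DiaryRecord(r.diary.participant_id, r.diary.system, r.diary.sensor_id,
                            r.diary.time, r.calculated, r.diary.visit),
                r.calculated, 0, r.in_window, r.reference,
            )
            for r in records
        ]
        assert summarize(forced).pct_match == 100.0


class TestStratifyByVisit:
    def test_visit_spans(self):
        assert visit_label(0.0) == 1
        assert visit_label(3 * 1440.0) == 1
        assert visit_label(4 * 1440.0) is None  # home
        assert visit_label(6 * 1440.0) == 2
        assert visit_label(14.5 * 1440.0) == 3

    def test_strata_union_is_total(self, small_study):
        records, _ = build_concordance(
            small_study.diary_for("FL"), small_study.traces, small_study.events, PROFILES["FL"]
        )
        by_visit = stratify_by_visit(records)
        n_home = sum(1 for r in records if r.diary.visit is None)
        assert sum(s.n for s in by_visit.values()) + n_home == len(records)
        assert set(by_visit) == {1, 2, 3}

    def test_single_visit_population(self):
        records, _ = build_concordance(
            [diary_rec(+1, visit=2)], {"P01-DG5-1": simple_trace()}, [], DEXCOM_G5, max_gap=40,
        )
        by_visit = stratify_by_visit(records)
        assert by_visit[2].n == 1
        assert by_visit[1].n == 0 and by_visit[3].n == 0


class TestParallelSensorAgreement:
    @staticmethod
    def stream(codes, sensor, t0=0.0):
        return [
            diary_rec(c, t=t0 + 60.0 * i, sensor=sensor) for i, c in enumerate(codes)
        ]

    def test_identical_streams(self):
        diary = self.stream([0, 1, -1, 2], "P01-DG5-1") + self.stream([0, 1, -1, 2], "P01-DG5-2")
        a = parallel_sensor_agreement(diary, "DG5")
        assert a.n_pairs == 4 and a.pct_identical == 100.0 and a.n_unpaired == 0

    def test_streams_offset_by_one_category(self):
        diary = self.stream([0, 1, -1], "P01-DG5-1") + self.stream([1, 2, 0], "P01-DG5-2")
        a = parallel_sensor_agreement(diary, "DG5")
        assert a.pct_identical == 0.0 and a.pct_off1 == 100.0

    def test_unpaired_records_dropped_and_counted(self):
        diary = self.stream([0, 1], "P01-DG5-1") + self.stream([0], "P01-DG5-2")
        a = parallel_sensor_agreement(diary, "DG5")
        assert a.n_pairs == 1 and a.n_unpaired == 1

    def test_three_sensors_rejected(self):
        diary = (
            self.stream([0], "P01-DG5-1")
            + self.stream([0], "P01-DG5-2")
            + self.stream([0], "P01-DG5-3")
        )
        with pytest.raises(ConfigurationError):
            parallel_sensor_agreement(diary, "DG5")

    def test_matches_brute_force_pair_count(self, small_study):
        diary = small_study.diary_for("FL")
        a = parallel_sensor_agreement(diary, "FL")
        rows = [(r.participant_id, r.sensor_id, r.time, r.recorded.code) for r in diary]
        diffs, unpaired = bf_pairs(rows)
        assert a.n_pairs == len(diffs) and a.n_unpaired == unpaired
        assert a.pct_identical == pytest.approx(
            _round1(100.0 * sum(1 for d in diffs if d == 0) / len(diffs))
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("system", ["DG5", "FL"])
    def test_pipeline_equals_brute_force_on_small_fixture(self, small_study, system):
        """Whole-pipeline pooled counts on a <=100-record fixture equal an
        independent naive reimplementation."""
        diary_rows, samples, events = study_to_plain(small_study, system)
        diary_rows = diary_rows[:100]
        profile = PROFILES[system]
        max_gap = 2.5 * profile.storage_interval
        diary = [r for r in small_study.diary_for(system)][:100]
        records, excl = build_concordance(
            diary, small_study.traces, small_study.events, profile, max_gap=max_gap
        )
        bf_results, bf_excl = bf_analyze(
            diary_rows, samples, events, system, max_gap=max_gap
        )
        n, match, off1, off2, inside = bf_tabulate(bf_results)
        assert len(records) == n and len(excl) == len(bf_excl)
        s = summarize(records)
        assert (s.n_match, s.n_off1, s.n_off2plus) == (match, off1, off2)
        assert sum(1 for r in records if r.in_window) == inside
        # Record-by-record equality, not just totals.
        got = [(r.diary.recorded.code, r.calculated.code, r.diff, r.in_window) for r in records]
        assert got == [tuple(r) for r in bf_results]
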