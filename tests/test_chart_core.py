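import dataclasses

import numpy as np
import pytest

from crmkit.chart_core import (
    CoupleCycle,
    CycleSource,
    DayRecord,
    FertilityStatus,
    InvalidObservationCode,
    NoChartError,
    PeakUnknownError,
    RuleTable,
    UnobservedDischargeError,
    ChartError,
    classify_days,
    cycles_from_day_records,
    flag_possible_pregnancy,
    identify_peak,
    identify_peak_day,
    impute_cycle_length,
    is_peak_type_mucus,
    read_chart_file,
    write_chart_file,
)

from .conftest import STANDARD_PATTERN, make_cycle, random_pattern

F, N, U = FertilityStatus.FERTILE, FertilityStatus.NON_FERTILE, FertilityStatus.UNKNOWN


# ---------------------------------------------------------------------------
# independent straight-line oracle for the default rule table

def oracle_classify(pattern: str) -> list[FertilityStatus]:
    """Brute-force re-statement of the default day rules, coded separately."""
    mucus_codes = "mP"
    peak = None
    for i, ch in enumerate(pattern):
        if ch == "P":
            peak = i + 1
    out = []
    for i, ch in enumerate(pattern):
        day = i + 1
        if ch == "u":
            out.append(U)
        elif ch in "HMLVB":
            out.append(F)
        elif ch in mucus_codes:
            out.append(F)
        else:  # dry
            if peak is not None and day > peak:
                if day - peak <= 3:
                    out.append(F)
                else:
                    out.append(N)
            else:
                recent_mucus = any(
                    pattern[j] in mucus_codes for j in range(max(0, i - 3), i)
                )
                out.append(F if recent_mucus else N)
    return out


class TestDayRecord:
    def test_invalid_bleeding_code(self):
        with pytest.raises(InvalidObservationCode):
            DayRecord("C1", 1, 1, bleeding="X")

    def test_invalid_discharge_code(self):
        with pytest.raises(InvalidObservationCode):
            DayRecord("C1", 1, 1, discharge="wet")

    def test_day_of_cycle_positive(self):
        with pytest.raises(ChartError):
            DayRecord("C1", 1, 0)

    def test_end_of_day_requires_intercourse(self):
        with pytest.raises(ChartError):
            DayRecord("C1", 1, 1, intercourse=False, intercourse_end_of_day=True)


class TestClassifyDays:
    def test_missing_observation_day_is_unknown(self):
        cycle = make_cycle("HMMLV" + "u" + "d" * 10)
        statuses = classify_days(cycle)
        assert statuses[5].status is U

    def test_dry_day_at_peak_plus_5_non_fertile(self, standard_cycle):
        statuses = classify_days(standard_cycle)
        peak = standard_cycle.peak_day
        assert statuses[peak + 5 - 1].status is N
        assert not statuses[peak + 5 - 1].end_of_day_only

    def test_peak_plus_4_is_end_of_day_only(self, standard_cycle):
        statuses = classify_days(standard_cycle)
        s = statuses[standard_cycle.peak_day + 4 - 1]
        assert s.status is N and s.end_of_day_only

    def test_peak_type_mucus_day_fertile(self, standard_cycle):
        statuses = classify_days(standard_cycle)
        for d, s in zip(standard_cycle.days, statuses):
            if d.discharge == "peak-type-mucus":
                assert s.status is F

    def test_prepeak_dry_end_of_day_only(self, standard_cycle):
        statuses = classify_days(standard_cycle)
        assert statuses[6].status is N and statuses[6].end_of_day_only

    def test_28_day_counts_match_oracle(self):
        cycle = make_cycle(STANDARD_PATTERN[:28])
        got = [s.status for s in classify_days(cycle)]
        want = oracle_classify(STANDARD_PATTERN[:28])
        assert got == want

    def test_no_chart_signals(self):
        cycle = CoupleCycle("C1", 1, 28, source=CycleSource.SOC_ONLY)
        with pytest.raises(NoChartError):
            classify_days(cycle)

    def test_partition_invariant(self, rng):
        for _ in range(50):
            cycle = make_cycle(random_pattern(rng, int(rng.integers(21, 36))))
            statuses = classify_days(cycle)
            assert len(statuses) == cycle.length_days

    def test_determinism(self, standard_cycle):
        a = classify_days(standard_cycle)
        b = classify_days(standard_cycle)
        assert a == b

    def test_monotone_missingness(self, rng):
        # adding an observation to an UNKNOWN day resolves it; removing all
        # observations always yields UNKNOWN
        pattern = "HMMLV" + "u" + "mmPP" + "d" * 10
        cycle = make_cycle(pattern)
        assert classify_days(cycle)[5].status is U
        resolved = make_cycle(pattern[:5] + "d" + pattern[6:])
        assert classify_days(resolved)[5].status is not U
        for day_idx in range(6, len(pattern)):
            blanked = make_cycle(pattern[:day_idx] + "u" + pattern[day_idx + 1 :])
            assert classify_days(blanked)[day_idx].status is U

    def test_peak_consistency(self, rng):
        for _ in range(100):
            cycle = make_cycle(random_pattern(rng, int(rng.integers(24, 36))))
            peak = cycle.peak_day
            if peak is None:
                continue
            for d, s in zip(cycle.days, classify_days(cycle)):
                if not d.observed:
                    continue
                if peak < d.day_of_cycle <= peak + 3:
                    assert s.status is F
                if d.day_of_cycle > peak + 4 and d.discharge == "dry" and d.bleeding == "none":
                    assert s.status is N

    def test_oracle_equivalence_1000_random_cycles(self, rng):
        for _ in range(1000):
            pattern = random_pattern(rng, int(rng.integers(21, 36)))
            cycle = make_cycle(pattern)
            got = [s.status for s in classify_days(cycle)]
            assert got == oracle_classify(pattern)


class TestPeakDay:
    def test_last_peak_type_day(self):
        cycle = make_cycle("HMMLV" + "dddddd" + "PPP" + "d" * 14)
        assert identify_peak_day(cycle) == 14

    def test_no_peak_type_absent(self):
        cycle = make_cycle("HMMLV" + "d" * 20)
        assert identify_peak_day(cycle) is None

    def test_double_peak_annotated(self):
        pattern = "HMMLV" + "dddddd" + "PP" + "dddd" + "P" + "d" * 10
        cycle = make_cycle(pattern)
        info = identify_peak(cycle)
        assert info.day == 18
        assert info.possible_double_peak

    def test_idempotent(self, standard_cycle):
        assert identify_peak(standard_cycle) == identify_peak(standard_cycle)


class TestIsPeakTypeMucus:
    @pytest.mark.parametrize(
        "discharge,expected",
        [("peak-type-mucus", True), ("dry", False), ("non-peak-mucus", False)],
    )
    def test_codes(self, discharge, expected):
        day = DayRecord("C1", 1, 10, discharge=discharge)
        assert is_peak_type_mucus(day) is expected

    def test_unobserved_signals(self):
        day = DayRecord("C1", 1, 10, bleeding="H", discharge="unobserved")
        with pytest.raises(UnobservedDischargeError):
            is_peak_type_mucus(day)


class TestImputeCycleLength:
    @pytest.mark.parametrize(
        "history,expected",
        [((28, 30, 29), 29), ((28,), 28), ((27, 28, 30, 33), 29)],
    )
    def test_median_half_up(self, history, expected):
        assert impute_cycle_length(history) == expected

    def test_empty_history_signals(self):
        with pytest.raises(ChartError):
            impute_cycle_length([])


class TestPregnancySurveillance:
    def test_boundary_postpeak_17(self):
        cycle = make_cycle("HMMLV" + "dddd" + "mm" + "PPP" + "d" * 17)
        assert cycle.peak_day == 14
        assert flag_possible_pregnancy(cycle, postpeak_threshold_days=17)

    def test_short_postpeak_on_time_menses(self):
        cycle = make_cycle("HMMLV" + "dddd" + "mm" + "PPP" + "d" * 12)
        assert not flag_possible_pregnancy(
            cycle, postpeak_threshold_days=17, next_cycle_start_delay=0
        )

    def test_no_peak_falls_back_to_menses_delay(self):
        cycle = make_cycle("HMMLV" + "d" * 25)
        assert cycle.peak_day is None
        assert flag_possible_pregnancy(cycle, next_cycle_start_delay=10)
        with pytest.raises(PeakUnknownError):
            flag_possible_pregnancy(cycle)

    def test_sensitivity_on_simulated_pregnancies(self):
        from crmkit.synthetic_cohort import SimConfig, generate_cohort

        mix = {
            "TRYING_HARD_CONCEIVE": 1.0, "CONCEIVE": 0.0, "NEUTRAL": 0.0,
            "AVOID": 0.0, "TRYING_HARD_AVOID": 0.0, "ABSTAIN": 0.0,
        }
        flagged = total = 0
        seed = 0
        while total < 1000:
            seed += 1
            cohort = generate_cohort(
                SimConfig(n_couples=400, seed=seed, intention_mix=mix,
                          chart_missing_prob=0.0, soc_and_chart_missing_prob=0.0)
            )
            for cycle in cohort.cycles:
                if cycle.pregnancy_in_cycle and cycle.peak_day is not None:
                    total += 1
                    flagged += flag_possible_pregnancy(cycle, postpeak_threshold_days=17)
        assert flagged / total >= 0.95


class TestChartIO:
    def test_round_trip_bit_exact(self, tmp_path, standard_cycle):
        days = list(standard_cycle.days)
        days[9] = dataclasses.replace(days[9], intercourse=True, intercourse_end_of_day=True)
        days[11] = dataclasses.replace(days[11], intercourse=True)
        p1 = tmp_path / "a.tsv"
        p2 = tmp_path / "b.tsv"
        write_chart_file(days, p1)
        back = read_chart_file(p1)
        assert back == days
        write_chart_file(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_bad_header_signals(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("foo\tbar\n")
        with pytest.raises(ChartError):
            read_chart_file(p)

    def test_cycles_from_day_records(self, standard_cycle):
        cycles = cycles_from_day_records(standard_cycle.days)
        assert len(cycles) == 1
        assert cycles[0].length_days == standard_cycle.length_days
        assert cycles[0].peak_day == standard_cycle.peak_day


class TestRuleTable:
    def test_yaml_round_trip(self, tmp_path):
        rt = RuleTable.default()
        p = tmp_path / "rules.yaml"
        rt.to_yaml(p)
        assert RuleTable.from_yaml(p) == rt

    def test_rules_are_data(self, standard_cycle):
        # swapping the post-peak count changes classification without code change
        rt = RuleTable(post_peak_fertile_days=2, end_of_day_only_post_peak_day=3)
        statuses = classify_days(standard_cycle, rt)
        peak = standard_cycle.peak_day
        assert statuses[peak + 3 - 1].status is FertilityStatus.NON_FERTILE
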