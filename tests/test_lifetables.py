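import numpy as np
import pytest

from crmkit.lifetables import (
    CoupleTimeline,
    CycleAtRisk,
    LifeTableError,
    MonthAtRisk,
    SensitivityCycle,
    build_timeline,
    months_at_risk,
    multiple_decrement,
    round_half_up,
    sensitivity_grid,
    single_decrement,
)


def constant_hazard_cycles(rng, n_couples, p, max_ordinal=13, stratum="S"):
    """Couples under constant per-cycle fecundability, no censoring."""
    out = []
    for i in range(n_couples):
        for ordinal in range(1, max_ordinal + 1):
            event = rng.random() < p
            out.append(CycleAtRisk(f"C{i}", ordinal, stratum, event))
            if event:
                break
    return out


class TestRounding:
    @pytest.mark.parametrize(
        "x,digits,expected",
        [(91.25, 1, 91.3), (34.84, 1, 34.8), (2.675, 2, 2.68), (71.97, 0, 72.0), (0.05, 1, 0.1)],
    )
    def test_half_up(self, x, digits, expected):
        assert round_half_up(x, digits) == expected


class TestSingleDecrement:
    def test_one_event_closed_form(self):
        cycles = []
        for i in range(10):
            if i == 0:
                cycles.append(CycleAtRisk(f"C{i}", 1, "S", True))
            else:
                cycles.extend(CycleAtRisk(f"C{i}", o, "S", False) for o in range(1, 14))
        result = single_decrement(cycles)["S"]
        assert result.cumulative_probability(13) == pytest.approx(0.1)

    def test_zero_events(self):
        cycles = [CycleAtRisk(f"C{i}", o, "S", False) for i in range(5) for o in range(1, 14)]
        assert single_decrement(cycles)["S"].cumulative_probability(13) == 0.0

    def test_constant_hazard_recovery(self, rng):
        p = 0.08
        cycles = constant_hazard_cycles(rng, 500, p)
        cp = single_decrement(cycles)["S"].cumulative_probability(13)
        truth = 1 - (1 - p) ** 13
        se = np.sqrt(truth * (1 - truth) / 500)
        assert abs(cp - truth) <= 3 * se

    def test_cp_non_decreasing(self, rng):
        cycles = constant_hazard_cycles(rng, 50, 0.1)
        result = single_decrement(cycles)["S"]
        cps = [result.cumulative_probability(k) for k in range(1, 14)]
        assert all(b >= a for a, b in zip(cps, cps[1:]))

    def test_matches_kaplan_meier_product_limit(self, rng):
        # independent product-limit oracle on 100 random small cohorts
        from lifelines import KaplanMeierFitter

        for rep in range(100):
            n = int(rng.integers(5, 25))
            durations, events, cycles = [], [], []
            for i in range(n):
                t = int(rng.integers(1, 14))
                e = bool(rng.random() < 0.5)
                durations.append(t)
                events.append(e)
                cycles.extend(
                    CycleAtRisk(f"C{i}", o, "S", e and o == t) for o in range(1, t + 1)
                )
            result = single_decrement(cycles)["S"]
            kmf = KaplanMeierFitter().fit(durations, events)
            km_surv = float(kmf.survival_function_.iloc[-1, 0])
            assert result.cumulative_probability(13) == pytest.approx(1 - km_surv, abs=1e-12)

    def test_risk_set_bookkeeping(self):
        cycles = [
            CycleAtRisk("A", 1, "S", False),
            CycleAtRisk("A", 2, "S", True),
            CycleAtRisk("B", 1, "S", False),
        ]
        rows = single_decrement(cycles)["S"].rows
        assert rows[0].n_at_risk == 2 and rows[0].events == 0 and rows[0].withdrawals == 1
        assert rows[1].n_at_risk == 1 and rows[1].events == 1

    def test_no_hidden_smoothing(self, rng):
        cycles = constant_hazard_cycles(rng, 30, 0.1)
        full = single_decrement(cycles)["S"]
        half = single_decrement(cycles[: len(cycles) // 2])["S"]
        for row_f, row_h in zip(full.rows, half.rows):
            if row_h.n_at_risk and row_h.n_at_risk == row_f.n_at_risk:
                assert row_h.q == row_f.q


class TestMultipleDecrement:
    def test_reduces_to_single_decrement(self):
        months, cycles = [], []
        rng = np.random.default_rng(5)
        for i in range(30):
            t = int(rng.integers(1, 13))
            e = bool(rng.random() < 0.6)
            months.extend(MonthAtRisk(f"C{i}", m) for m in range(1, t))
            months.append(MonthAtRisk(f"C{i}", t, "preg" if e else None))
            cycles.extend(
                CycleAtRisk(f"C{i}", o, "S", e and o == t) for o in range(1, t + 1)
            )
        md = multiple_decrement(months, max_ordinal=12)
        sd = single_decrement(cycles, max_ordinal=12)["S"]
        assert md.net_rates["preg"] / 100 == pytest.approx(sd.cumulative_probability(12))

    def test_symmetric_causes(self):
        months = []
        for i in range(20):
            months.append(MonthAtRisk(f"A{i}", 1, "x"))
            months.append(MonthAtRisk(f"B{i}", 1, "y"))
        md = multiple_decrement(months)
        assert md.net_rates["x"] == pytest.approx(md.net_rates["y"])

    def test_hand_enumerated_five_couples(self):
        # 5 couples: cause a at month 1; cause b at month 2; censor after
        # month 2; cause a at month 3; survive 3 months.
        months = [
            MonthAtRisk("C1", 1, "a"),
            MonthAtRisk("C2", 1), MonthAtRisk("C2", 2, "b"),
            MonthAtRisk("C3", 1), MonthAtRisk("C3", 2),
            MonthAtRisk("C4", 1), MonthAtRisk("C4", 2), MonthAtRisk("C4", 3, "a"),
            MonthAtRisk("C5", 1), MonthAtRisk("C5", 2), MonthAtRisk("C5", 3),
        ]
        # hand computation: q_a1=1/5, p1=4/5; q_b2=1/4, p2=3/4; q_a3=1/2, p3=1/2
        # NR_a = 1/5 + (4/5)(3/4)(1/2) = 0.2 + 0.3 = 0.5
        # NR_b = (4/5)(1/4) = 0.2 ; continuation = (4/5)(3/4)(1/2) = 0.3
        md = multiple_decrement(months, max_ordinal=3)
        assert md.net_rates["a"] == pytest.approx(50.0)
        assert md.net_rates["b"] == pytest.approx(20.0)
        assert md.continuation == pytest.approx(0.3)

    def test_accounting_identity(self, rng):
        for rep in range(20):
            months = []
            for i in range(int(rng.integers(3, 40))):
                t = int(rng.integers(1, 13))
                cause = rng.choice(["a", "b", "c", None])
                months.extend(MonthAtRisk(f"C{i}", m) for m in range(1, t))
                months.append(MonthAtRisk(f"C{i}", t, cause))
            md = multiple_decrement(months)
            assert abs(md.accounting_identity() - 1.0) < 1e-9

    def test_half_unit_correction_raises_rates(self):
        months = [
            MonthAtRisk("C1", 1, "a"),
            MonthAtRisk("C2", 1),  # withdrawal at month 1
            MonthAtRisk("C3", 1), MonthAtRisk("C3", 2),
        ]
        full = multiple_decrement(months)
        half = multiple_decrement(months, half_unit_correction=True)
        assert half.net_rates["a"] > full.net_rates["a"]
        assert abs(half.accounting_identity() - 1.0) < 1e-9


class TestTimeline:
    def test_analytic_start_later_of_consent_and_intercourse(self):
        # consent mid-cycle-2, first intercourse in cycle 4
        tl = build_timeline("C1", [0, 29, 58, 87, 116], consent_day=40,
                            first_intercourse_cycle=4, exit_day=200, exit_reason="pregnancy")
        assert tl.analytic_start == 87

    def test_consent_only(self):
        tl = build_timeline("C1", [0, 29], consent_day=10,
                            first_intercourse_cycle=1, exit_day=100, exit_reason="stopped")
        assert tl.analytic_start == 0

    def test_exit_before_entry_signals(self):
        with pytest.raises(LifeTableError):
            build_timeline("C1", [0, 29], consent_day=35,
                           first_intercourse_cycle=2, exit_day=10, exit_reason="lost")

    def test_months_at_risk_pregnancy(self):
        tl = CoupleTimeline("C1", 0, 200, "pregnancy")
        months = months_at_risk(tl, pregnancy_day=65, cause="ACHIEVING")
        assert [m.ordinal for m in months] == [1, 2, 3]
        assert months[-1].cause == "ACHIEVING"

    def test_months_at_risk_censoring(self):
        tl = CoupleTimeline("C1", 0, 365, "completed_year")
        months = months_at_risk(tl, pregnancy_day=None, cause=None)
        assert [m.ordinal for m in months] == list(range(1, 12 + 1))
        assert all(m.cause is None for m in months)

    def test_ordinal_month_binning(self):
        tl = CoupleTimeline("C1", 0, 365, "completed_year")
        assert tl.ordinal_month(0) == 1
        assert tl.ordinal_month(30) == 1
        assert tl.ordinal_month(31) == 2


class TestSensitivityGrid:
    def _cycles(self, barrier=False, prospective=True):
        out = []
        for i in range(12):
            event = i == 0
            out.append(
                SensitivityCycle(f"C{i}", 1, "Avoiding", trying_hard_avoid=i % 2 == 0,
                                 event=event, prospective=prospective,
                                 barrier_or_withdrawal=barrier)
            )
        return out

    def test_barrier_free_arms_identical(self):
        grid = sensitivity_grid(self._cycles(barrier=False))
        g = grid.set_index(["window", "barrier", "stratum"])
        for w in ("<=11d", "all"):
            ex = g.loc[(w, "excluded", "Avoiding")]
            inc = g.loc[(w, "included", "Avoiding")]
            assert ex["cp13"] == inc["cp13"] and ex["cycles"] == inc["cycles"]

    def test_all_prospective_window_arms_identical(self):
        grid = sensitivity_grid(self._cycles(prospective=True))
        g = grid.set_index(["window", "barrier", "stratum"])
        for b in ("excluded", "included"):
            assert (
                g.loc[("<=11d", b, "Avoiding")]["cp13"]
                == g.loc[("all", b, "Avoiding")]["cp13"]
            )

    def test_all_barrier_excluded_arm_empty(self):
        grid = sensitivity_grid(self._cycles(barrier=True))
        g = grid.set_index(["window", "barrier", "stratum"])
        assert g.loc[("all", "excluded", "Avoiding")]["cycles"] == 0
        assert g.loc[("all", "included", "Avoiding")]["cycles"] == 12

    def test_grid_shape(self):
        grid = sensitivity_grid(self._cycles())
        assert len(grid) == 16  # 2 windows x 2 barrier arms x 4 strata


class TestParameterRecovery:
    def test_unbiased_against_generator_truth(self):
        # estimate CP(13) from generated cohorts and compare with the
        # generator's exact truth over replicate cohorts
        from crmkit.intentions import IntentionLevel, collapse_intentions
        from crmkit.synthetic_cohort import SimConfig, generate_cohort, ground_truth_report

        diffs = []
        for seed in range(25):
            cohort = generate_cohort(SimConfig(n_couples=40, seed=seed))
            truth = ground_truth_report(cohort)["true_cp"]
            cycles = [
                CycleAtRisk(
                    row.couple_id,
                    row.ordinal,
                    collapse_intentions(IntentionLevel[row.intention], "lifetable"),
                    bool(row.conceived),
                )
                for row in cohort.truth.itertuples()
            ]
            result = single_decrement(cycles).get("Avoiding")
            if result is None or "Avoiding" not in truth:
                continue
            diffs.append(result.cumulative_probability(13) - truth["Avoiding"])
        mean = float(np.mean(diffs))
        se = float(np.std(diffs, ddof=1) / np.sqrt(len(diffs)))
        assert abs(mean) <= 3 * se + 1e-12
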