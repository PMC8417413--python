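"""Rule-engine tests: CHO-intake algorithm, consensus guidelines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import t1dex as tx
from t1dex.strategies import (StrategyContext, consensus_onset_action,
                              consensus_during_schedule,
                              consensus_during_total, consensus_end_action,
                              consensus_cho_plan, get_strategy)
from conftest import exercise_day


def ctx(G, trend=0.0, since_snack=math.inf, time=600.0, condition="low"):
    return StrategyContext(time=time, G=G, trend=trend, session=None,
                           time_since_last_snack=since_snack,
                           bolus_times=[], insulin_condition=condition)


class TestCHOAlgorithm:
    @pytest.mark.parametrize("G,trend,since,expected", [
        (100.0, -7.0, math.inf, (16.0, False)),   # one-arrow drop
        (100.0, -12.0, math.inf, (20.0, False)),  # two-arrow drop
        (85.0, +3.0, math.inf, (16.0, False)),    # below 90, trend ignored
        (130.0, -12.0, math.inf, (0.0, False)),   # above 126: nothing
        (115.0, -6.0, math.inf, (8.0, False)),
        (115.0, -4.0, math.inf, (0.0, False)),    # drop below threshold
        (100.0, -7.0, 10.0, (0.0, False)),        # recent snack blocks
        (100.0, -7.0, 25.0, (16.0, False)),       # spacing satisfied
        (65.0, 0.0, math.inf, (0.0, True)),       # suspend below 70
        (95.0, -2.0, math.inf, (0.0, False)),     # slow drop 90-110: nothing
    ])
    def test_decision_table(self, G, trend, since, expected):
        assert tx.cho_algorithm_step(ctx(G, trend, since)) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(20.0, 400.0), st.floats(-30.0, 30.0),
           st.floats(0.0, 19.9))
    def test_never_snacks_above_126_or_within_spacing(self, G, trend, since):
        grams, _ = tx.cho_algorithm_step(ctx(G, trend))
        if G >= 126.0:
            assert grams == 0.0
        grams2, _ = tx.cho_algorithm_step(ctx(G, trend, since))
        assert grams2 == 0.0

    def test_snack_spacing_in_simulation(self, params):
        """No two snacks of the CHO algorithm fall within 20 min."""
        res = tx.simulate(exercise_day(570.0, duration=120.0, HR=160.0),
                          params, get_strategy("cho_algorithm"))
        times = sorted(e.time for e in res.log.snacks())
        assert times, "scenario expected to trigger snacks"
        assert all(b - a >= 20.0 for a, b in zip(times, times[1:]))


class TestConsensusReduction:
    @pytest.mark.parametrize("HR,dur,gap,expected", [
        (120.0, 60.0, 105.0, 0.25),
        (140.0, 90.0, 60.0, 0.75),
        (120.0, 60.0, 165.0, 0.0),    # gap beyond 120 min
        (120.0, 75.0, 30.0, 0.50),
        (140.0, 45.0, 30.0, 0.50),
        (160.0, 30.0, 30.0, 0.75),
        (160.0, 90.0, 30.0, 0.75),
        (95.0, 60.0, 30.0, 0.0),      # below the table's intensity range
        (120.0, 60.0, -10.0, 0.0),    # bolus after exercise start
    ])
    def test_table(self, HR, dur, gap, expected):
        assert tx.consensus_bolus_reduction(HR, dur, gap) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(60.0, 220.0), st.floats(1.0, 240.0),
           st.floats(-500.0, 500.0))
    def test_fraction_domain(self, HR, dur, gap):
        assert tx.consensus_bolus_reduction(HR, dur, gap) in (
            0.0, 0.25, 0.5, 0.75)


class TestInsulinCondition:
    @pytest.mark.parametrize("bolus_times,start,expected", [
        ([405.0], 510.0, "high"),    # gap 105 min
        ([405.0], 570.0, "low"),     # gap 165 min
        ([], 510.0, "low"),
        ([510.0], 510.0, "high"),    # gap 0
    ])
    def test_classification(self, bolus_times, start, expected):
        assert tx.classify_insulin_condition(bolus_times, start) == expected


class TestConsensusCHO:
    def test_onset_actions(self):
        assert consensus_onset_action(85.0, "low") == (15.0, True)
        assert consensus_onset_action(85.0, "high") == (25.0, True)
        assert consensus_onset_action(100.0, "low") == (10.0, False)
        assert consensus_onset_action(140.0, "high") == (0.0, False)

    @pytest.mark.parametrize("dur,cond,variant,total", [
        (90.0, "high", "low", 90.0),     # 60 g/h for 1.5 h
        (45.0, "low", "high", 11.25),    # 15 g/h for 0.75 h
        (60.0, "low", "low", 10.0),      # 10 g/h, bracket closed at 60
        (30.0, "low", "low", 0.0),
        (30.0, "high", "high", 30.0),    # short-session total, not a rate
        (120.0, "high", "high", 140.0),  # 70 g/h for 2 h
    ])
    def test_during_totals(self, dur, cond, variant, total):
        assert consensus_during_total(dur, cond, variant) == \
            pytest.approx(total)
        schedule = consensus_during_schedule(dur, cond, variant)
        assert sum(g for _, g in schedule) == pytest.approx(total)
        assert all(0.0 < off <= dur for off, _ in schedule)

    def test_end_action(self):
        assert consensus_end_action(85.0) == 20.0
        assert consensus_end_action(95.0) == 0.0

    def test_full_plan_assembly(self):
        session = tx.ExerciseSession(start=510.0, duration=90.0, HR=140.0)
        context = StrategyContext(time=510.0, G=85.0, trend=-3.0,
                                  session=session,
                                  time_since_last_snack=float("inf"),
                                  bolus_times=[405.0],
                                  insulin_condition="high")
        plan = consensus_cho_plan(context, variant="low")
        assert plan.onset_grams == 25.0 and plan.delay_start
        assert sum(g for _, g in plan.during) == pytest.approx(90.0)
        assert plan.end_grams_if_low == 20.0

    def test_exercise_delayed_until_glucose_recovers(self, params):
        """A session planned at low glucose is postponed and keeps its
        duration once glucose exceeds 90 mg/dl."""
        # drive glucose low before the planned start with an oversized bolus
        plan = tx.DayPlan(
            boluses=[tx.PlannedBolus(time=0.0, carbs_g=75.0)],
            exercise=[tx.ExerciseSession(start=240.0, duration=30.0,
                                         HR=120.0)],
            meals=[tx.Meal(time=330.0, carbs_mg=80000.0, tau_max=20.0)])
        res = tx.simulate(plan, params, get_strategy("consensus_low"))
        t, g = res.trajectory.time, res.trajectory.G
        assert g[t == 240.0][0] < 90.0, "setup must start hypoglycemic"
        actions = [e.action for e in res.log.entries]
        assert "exercise_delay" in actions
        hr = res.trajectory.HR
        assert hr.max() == 120.0, "session eventually starts"
        # duration preserved: contiguous block of elevated heart rate
        assert (hr > params.HRb).sum() == 30


class TestDegeneracy:
    def test_all_strategies_reduce_to_no_adjustment(self, params):
        """With every threshold out of reach (glucose high, low intensity,
        bolus gap beyond 120 min) all strategies match the baseline."""
        ref = None
        for name in ("none", "cho_algorithm", "consensus_low",
                     "consensus_high"):
            res = tx.simulate(exercise_day(180.0, duration=30.0, HR=105.0),
                              params, get_strategy(name))
            t, g = res.trajectory.time, res.trajectory.G
            sess = g[(t >= 180.0) & (t <= 210.0)]
            assert sess.min() > 130.0, "thresholds must stay unreachable"
            assert not res.log.entries
            if ref is None:
                ref = g
            else:
                assert np.abs(g - ref).max() < 1e-5
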