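"""Executable study scenarios: timing sweep, intensity-duration grids,
virtual population, and the sensitivity-analysis setup.

Every experiment is generated here as data — (day plan, parameter set,
strategy) triples — so the same scenario definitions drive simulation,
reporting and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import PatientParams, ExerciseSession, clock_to_minutes
from .therapy import DayPlan, standard_day
from .strategies import STRATEGY_NAMES


@dataclass(frozen=True)
class ScenarioRun:
    """One simulatable unit of a scenario set."""

    name: str
    plan: DayPlan
    params: PatientParams
    strategy: str
    axes: dict = field(default_factory=dict)   # sweep coordinates


@dataclass
class ScenarioSet:
    name: str
    runs: list

    def __iter__(self):
        return iter(self.runs)

    def __len__(self):
        return len(self.runs)


def _exercise_day(start: float, duration: float, HR: float,
                  lunch_time: str | None = None) -> DayPlan:
    plan = standard_day(lunch_time=lunch_time)
    plan.exercise.append(ExerciseSession(start=start, duration=duration,
                                         HR=HR))
    return plan


TIMING_SWEEP_STARTS = tuple(clock_to_minutes("13:30") + 30.0 * i
                            for i in range(9))   # 13:30h ... 17:30h
TIMING_SWEEP_HR = 120.0
TIMING_SWEEP_DURATION = 60.0


def timing_sweep(strategies=STRATEGY_NAMES) -> ScenarioSet:
    """Exercise-start sweep: 60 min at 120 bpm from 13:30h to 17:30h in
    30-min steps, crossed with the adjustment strategies."""
    params = PatientParams()
    runs = []
    for start in TIMING_SWEEP_STARTS:
        for strat in strategies:
            plan = _exercise_day(start, TIMING_SWEEP_DURATION,
                                 TIMING_SWEEP_HR)
            runs.append(ScenarioRun(
                name=f"timing_{int(start)}_{strat}",
                plan=plan, params=params, strategy=strat,
                axes={"start": start, "strategy": strat}))
    return ScenarioSet(name="timing_sweep", runs=runs)


GRID_HRS = (120.0, 140.0, 160.0)
GRID_DURATIONS = tuple(30.0 + 15.0 * i for i in range(7))   # 30 ... 120 min

#: exercise start time and lunch placement per numbered scenario
SCENARIO_TIMING = {
    1: {"exercise_start": clock_to_minutes("12:00"), "lunch_time": "14:30"},
    2: {"exercise_start": clock_to_minutes("14:30"), "lunch_time": None},
    3: {"exercise_start": clock_to_minutes("15:30"), "lunch_time": None},
}


def scenario_plan(scenario: int, duration: float, HR: float) -> DayPlan:
    """Day plan for one cell of a numbered scenario grid.

    Scenario 1: exercise at 12:00h in the postabsorptive state, lunch
    postponed to 14:30h.  Scenario 2: exercise at 14:30h, shortly after
    lunch (high insulin condition, bolus reduction applies).  Scenario 3:
    exercise at 15:30h (low insulin condition, no bolus reduction).
    """
    cfg = SCENARIO_TIMING[scenario]
    return _exercise_day(cfg["exercise_start"], duration, HR,
                         lunch_time=cfg["lunch_time"])


def scenario_grid(scenario: int,
                  strategies=STRATEGY_NAMES,
                  params: PatientParams | None = None) -> ScenarioSet:
    """Full intensity x duration x strategy factorial for one scenario."""
    if scenario not in SCENARIO_TIMING:
        raise ValueError("scenario must be 1, 2 or 3")
    params = params or PatientParams()
    runs = []
    for HR in GRID_HRS:
        for dur in GRID_DURATIONS:
            for strat in strategies:
                runs.append(ScenarioRun(
                    name=f"s{scenario}_hr{int(HR)}_d{int(dur)}_{strat}",
                    plan=scenario_plan(scenario, dur, HR),
                    params=params, strategy=strat,
                    axes={"HR": HR, "duration": dur, "strategy": strat}))
    return ScenarioSet(name=f"scenario_{scenario}", runs=runs)


#: parameters perturbed when sampling a virtual population
POPULATION_VARIED = ("p1", "p3", "alpha", "beta")
POPULATION_SD_FRACTION = 0.20
POPULATION_SIZE = 100
#: default population exercise prescription
POPULATION_DURATION = 90.0
POPULATION_HR = 140.0


def sample_population(n_subjects: int = POPULATION_SIZE,
                      sd_fraction: float = POPULATION_SD_FRACTION,
                      seed: int | None = None) -> list:
    """Draw virtual subjects around the nominal parameter set.

    Glucose effectiveness (p1), insulin sensitivity (p3), the
    exercise-driven insulin-sensitivity gain (alpha) and exercise glucose
    clearance (beta) are each drawn independently from a normal
    distribution with SD ``sd_fraction`` of the nominal value; draws <= 0
    are rejected and redrawn.  All other parameters stay nominal.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be > 0")
    if not 0 <= sd_fraction < 1:
        raise ValueError("sd_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    nominal = PatientParams()
    subjects = []
    for _ in range(n_subjects):
        changes = {}
        for name in POPULATION_VARIED:
            mu = getattr(nominal, name)
            val = rng.normal(mu, sd_fraction * mu) if sd_fraction > 0 else mu
            while val <= 0:
                val = rng.normal(mu, sd_fraction * mu)
            changes[name] = float(val)
        subjects.append(nominal.replace(**changes))
    return subjects


def population_scenarios(subjects, scenario: int,
                         duration: float = POPULATION_DURATION,
                         HR: float = POPULATION_HR,
                         strategies=STRATEGY_NAMES) -> ScenarioSet:
    """Population study: every subject x strategy on one scenario cell."""
    runs = []
    for i, subj in enumerate(subjects):
        for strat in strategies:
            runs.append(ScenarioRun(
                name=f"s{scenario}_subj{i:03d}_{strat}",
                plan=scenario_plan(scenario, duration, HR),
                params=subj, strategy=strat,
                axes={"subject": i, "strategy": strat}))
    return ScenarioSet(name=f"population_s{scenario}", runs=runs)


# ----------------------------------------------------------- sensitivity
#: model parameters varied in the global sensitivity analysis: the
#: glucose-regulation and insulin-kinetics constants plus the glucose
#: distribution volume.  The integer Hill exponent n, the therapy constants
#: (ICR, CF, BW, HRb, Ib, Gt) and the meal-shape inputs (f_bio, tau_max) are
#: held fixed; the meal composition describes the scenario, not the subject.
GSA_PARAMETERS = ("p1", "p2", "p3", "Gb", "alpha", "beta", "tauHR", "tau",
                  "a", "Vg", "k21", "kd", "ka", "ke", "Vi")
GSA_HALF_WIDTH = 0.20
GSA_EXERCISE_START = clock_to_minutes("15:30")
GSA_EXERCISE_DURATION = 60.0
GSA_EXERCISE_HR = 120.0
GSA_TIMING_BOUNDS = (clock_to_minutes("13:30"), clock_to_minutes("17:30"))
#: sample budgets of the full-scale experiments
GSA_TARGET_EVALS = 51_000
GSA_TARGET_EVALS_TIMING = 54_000


def sensitivity_scenario(vary_timing: bool = False
                         ) -> tuple[DayPlan, dict]:
    """Base day plan and uniform parameter box for the sensitivity analysis.

    The day is the standard day plus a 60-min session at 120 bpm starting
    15:30h with no treatment adjustment.  Each continuous model parameter
    varies uniformly within +/-20% of nominal; with ``vary_timing`` the
    exercise start time becomes an additional uniform input on
    [13:30h, 17:30h].
    """
    plan = _exercise_day(GSA_EXERCISE_START, GSA_EXERCISE_DURATION,
                         GSA_EXERCISE_HR)
    nominal = PatientParams().to_dict()
    nominal["tau_max"] = plan.meals[0].tau_max
    bounds = {}
    for name in GSA_PARAMETERS:
        v = nominal[name]
        bounds[name] = (v * (1.0 - GSA_HALF_WIDTH),
                        v * (1.0 + GSA_HALF_WIDTH))
    if vary_timing:
        bounds["t_exercise"] = GSA_TIMING_BOUNDS
    return plan, bounds


def list_scenarios() -> dict:
    """Names and brief descriptions of the runnable scenario sets."""
    return {
        "timing_sweep": "9 exercise start times x 4 strategies, 60 min at "
                        "120 bpm",
        "scenario_1": "postabsorptive exercise at 12:00h, lunch at 14:30h; "
                      "3 HR x 7 durations x 4 strategies",
        "scenario_2": "exercise at 14:30h with prior bolus reduction; "
                      "3 HR x 7 durations x 4 strategies",
        "scenario_3": "exercise at 15:30h, low insulin condition; "
                      "3 HR x 7 durations x 4 strategies",
        "population": "100 virtual subjects, 90 min at 140 bpm per scenario",
        "gsa": "Sobol sensitivity of TIR and LBGI, +/-20% parameter box",
    }
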