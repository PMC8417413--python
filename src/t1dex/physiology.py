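"""Glucose-insulin-exercise physiology and the event-driven day simulator.

The model couples four published components into one ODE system with eight
states:

* a minimal-model glucose-insulin core: remote insulin action ``X`` [1/min]
  acting on plasma glucose ``G`` [mg/dl],
* an exercise extension in which over-basal heart rate drives an energy-
  expenditure state ``Y`` [bpm], a slowly decaying switch ``Z`` in [0, 1]
  and the integrated over-basal heart rate ``W`` [bpm·min], which together
  scale insulin action by ``(1 + alpha·W·Z)`` and add an insulin-independent
  clearance ``beta·Y·G``,
* a gamma-shaped meal glucose appearance rate ``Ra(t)``,
* two subcutaneous insulin compartments ``x1``, ``x2`` [µU] feeding plasma
  insulin ``Ic`` [µU/ml].

Plasma insulin is decomposed as ``I = It + Ic`` where ``It`` is the constant
concentration required to hold fasting glucose at the therapy target ``Gt``;
the ODE sees the over-basal difference ``dI = It + Ic - Ib``.

Simulation runs over a 24 h day starting at 06:00 (t = 0 min).  Discrete
events — meals, bolus injections, exercise start/stop, strategy actions —
break the integration into smooth segments; an adaptive stiff-capable solver
(LSODA) integrates each segment and the solution is reported on a uniform
1-min output grid.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import (PatientParams, Meal, Bolus, ExerciseSession,
                     minutes_to_clock)
from .therapy import DayPlan, PlannedBolus, BolusRequest, compute_bolus
from .strategies import (Strategy, NoAdjustment, StrategyContext,
                         AdjustmentLog, classify_insulin_condition)

# state vector layout
IX_X, IX_G, IX_Y, IX_Z, IX_W, IX_X1, IX_X2, IX_IC = range(8)
STATE_NAMES = ("X", "G", "Y", "Z", "W", "x1", "x2", "Ic")

MICROUNITS_PER_UNIT = 1.0e6  # 1 U of insulin = 10^6 µU


def exercise_switch(Y: float, params: PatientParams) -> float:
    """Sigmoidal exercise-onset switch f(Y) in [0, 1).

    Rises from 0 to 1 as the energy-expenditure state Y exceeds the fraction
    ``a`` of the basal heart rate; the Hill exponent ``n`` sets the
    steepness.
    """
    if Y <= 0:
        return 0.0
    r = (Y / (params.a * params.HRb)) ** params.n
    return r / (1.0 + r)


def meal_ra(t_since_meal, meal: Meal):
    """Glucose appearance rate [mg/min] at ``t_since_meal`` minutes after a meal.

    Gamma-shaped kernel f·D·t·exp(-t/tau_max)/tau_max², peaking at
    t = tau_max and integrating to f·D over [0, inf).
    """
    t = np.asarray(t_since_meal, dtype=float)
    out = (meal.f_bio * meal.carbs_mg * t
           * np.exp(-t / meal.tau_max) / meal.tau_max ** 2)
    out = np.where(t >= 0, out, 0.0)
    return float(out) if np.isscalar(t_since_meal) else out


def target_insulin(params: PatientParams) -> float:
    """Plasma insulin concentration It [µU/ml] holding fasting glucose at Gt.

    Closed form from the fasting steady state of the glucose-insulin core:
    It = Ib + (p2/p3)·p1·(Gb - Gt)/Gt.
    """
    if params.Gb <= params.Gt:
        raise ValueError("Gb <= Gt: no over-basal insulin required")
    return params.Ib + (params.p2 / params.p3) * params.p1 * (
        params.Gb - params.Gt) / params.Gt


def basal_insulin_action(params: PatientParams) -> float:
    """Steady-state remote action Xb [1/min] of the basal insulin concentration."""
    return (params.p3 / params.p2) * params.Ib


def steady_state(params: PatientParams) -> np.ndarray:
    """Fasting equilibrium state with G = Gt, no meals, boluses or exercise."""
    y = np.zeros(8)
    y[IX_G] = params.Gt
    y[IX_X] = params.p1 * (params.Gb - params.Gt) / params.Gt
    return y


def ode_rhs(t: float, y: np.ndarray, params: PatientParams, hr: float,
            ra, It: float, Xb: float) -> np.ndarray:
    """Time derivatives of the 8 model states.

    ``hr`` is the (segment-constant) heart-rate input [bpm]; ``ra`` maps
    absolute time to the total meal appearance rate [mg/min].
    """
    X, G, Y, Z, W, x1, x2, Ic = y
    p = params
    dI = It + Ic - p.Ib
    fY = exercise_switch(Y, p)
    exfac = p.alpha * W * Z
    d = np.empty(8)
    d[IX_X] = -p.p2 * X + p.p3 * dI
    d[IX_G] = (-p.p1 * (G - p.Gb)
               - (1.0 + exfac) * X * G
               - exfac * Xb * G
               - p.beta * Y * G
               + ra(t) / (p.Vg * p.BW))
    d[IX_Y] = (-(Y) + (hr - p.HRb)) / p.tauHR
    d[IX_Z] = -(fY + 1.0 / p.tau) * Z + fY
    d[IX_W] = hr - p.HRb
    d[IX_X1] = -p.k21 * x1
    d[IX_X2] = p.k21 * x1 - (p.kd + p.ka) * x2
    d[IX_IC] = p.ka / (p.Vi * p.BW) * x2 - p.ke * Ic
    return d


@dataclass
class Trajectory:
    """Model states and heart-rate input on a uniform output grid."""

    time: np.ndarray                 # min since 06:00
    states: np.ndarray               # (nt, 8) in STATE_NAMES order
    HR: np.ndarray                   # bpm input at each grid point

    @property
    def G(self) -> np.ndarray:
        return self.states[:, IX_G]

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def to_dataframe(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_min", self.time)
        df.insert(1, "clock_time", [minutes_to_clock(t) for t in self.time])
        df["HR"] = self.HR
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class SimulationResult:
    trajectory: Trajectory
    log: AdjustmentLog
    boluses: list  # realized Bolus events


# event kinds, in tie-break priority order at equal time
_EV_MEAL, _EV_BOLUS, _EV_SNACK, _EV_POLL, _EV_EX_END, _EV_EX_START, _EV_DELAY = range(7)

_POLL_STEP = 5.0       # min between strategy evaluations during exercise
_DELAY_CAP = 120.0     # min: maximum postponement before a session is cancelled


@dataclass
class _SessionState:
    session: ExerciseSession
    started: bool = False
    start_time: float = math.nan   # actual start after any delay
    end_time: float = math.nan
    running: bool = False
    suspended: bool = False
    cancelled: bool = False
    onset_done: bool = False


class Simulator:
    """Event-driven integrator for one simulated day.

    Integrates the physiology piecewise between discrete events with LSODA
    (rtol 1e-8, atol 1e-10 by default) and restarts at every event boundary.
    Treatment-adjustment strategies are consulted at bolus time (reduction),
    at exercise onset (snack/delay), on a 5-min grid during exercise
    (CGM-style polling) and at session end.
    """

    def __init__(self, params: PatientParams | None = None, *,
                 rtol: float = 1e-8, atol: float = 1e-10,
                 output_step: float = 1.0):
        if output_step <= 0:
            raise ValueError("output_step must be > 0")
        self.params = params or PatientParams()
        self.rtol = rtol
        self.atol = atol
        self.output_step = output_step

    # ------------------------------------------------------------------ run
    def run(self, plan: DayPlan, strategy: Strategy | None = None
            ) -> SimulationResult:
        p = self.params
        strategy = strategy or NoAdjustment()
        plan.validate()

        It = target_insulin(p)
        Xb = basal_insulin_action(p)

        n_grid = int(round(plan.horizon / self.output_step)) + 1
        grid = np.arange(n_grid) * self.output_step
        states = np.empty((n_grid, 8))
        hr_grid = np.empty(n_grid)

        y = steady_state(p)
        states[0] = y
        hr_grid[0] = p.HRb
        filled = 0                   # highest grid index written

        heap: list = []
        seq = 0

        def push(time, kind, payload=None):
            nonlocal seq
            heapq.heappush(heap, (time, kind, seq, payload))
            seq += 1

        active_meals: list[Meal] = list(plan.extra_meals)
        for m in plan.meals:
            push(m.time, _EV_MEAL, m)
        for b in plan.boluses:
            push(b.time, _EV_BOLUS, b)
        sess_states = {}
        for s in plan.exercise:
            sess_states[id(s)] = _SessionState(s)
            push(s.start, _EV_EX_START, s)

        hr_now = p.HRb
        log = AdjustmentLog()
        boluses: list[Bolus] = []
        last_snack: float | None = None

        def ra_total(t):
            tot = 0.0
            for m in active_meals:
                if t >= m.time:
                    tot += meal_ra(t - m.time, m)
            return tot

        def g_at(t):
            """Simulated glucose at a past grid-covered time (interpolated)."""
            if filled == 0:
                return states[0, IX_G]
            return float(np.interp(t, grid[:filled + 1],
                                   states[:filled + 1, IX_G]))

        def add_snack(t, grams, trigger_g, trend):
            nonlocal last_snack
            active_meals.append(Meal(time=t, carbs_mg=grams * 1000.0,
                                     tau_max=plan.snack_tau_max,
                                     f_bio=p.f_bio))
            last_snack = t
            log.add(t, "snack", grams, trigger_g, trend)

        def context(t, ss: _SessionState | None):
            g = y[IX_G]
            trend = (g - g_at(t - _POLL_STEP)) if t >= _POLL_STEP else 0.0
            btimes = [b.time for b in boluses]
            ref = ss.session.start if ss is not None else t
            cond = classify_insulin_condition(btimes, ref)
            since_snack = math.inf if last_snack is None else t - last_snack
            return StrategyContext(
                time=t, G=g, trend=trend,
                session=ss.session if ss else None,
                time_since_last_snack=since_snack,
                bolus_times=btimes, insulin_condition=cond)

        def integrate_to(t0, t1):
            nonlocal filled
            if t1 <= t0 + 1e-12:
                return
            sol = solve_ivp(ode_rhs, (t0, t1), y, method="LSODA",
                            rtol=self.rtol, atol=self.atol,
                            dense_output=True,
                            args=(p, hr_now, ra_total, It, Xb))
            if not sol.success:      # pragma: no cover - solver failure
                raise RuntimeError(f"integration failed on [{t0}, {t1}]: "
                                   f"{sol.message}")
            i0 = int(math.floor(t0 / self.output_step)) + 1
            i1 = int(math.floor(t1 / self.output_step + 1e-9))
            if i1 >= i0:
                ts = grid[i0:i1 + 1]
                states[i0:i1 + 1] = sol.sol(ts).T
                hr_grid[i0:i1 + 1] = hr_now
                filled = max(filled, i1)
            y[:] = sol.y[:, -1]

        def start_session(t, ss: _SessionState):
            nonlocal hr_now
            ss.started = True
            ss.running = True
            ss.start_time = t
            ss.end_time = t + ss.session.duration
            hr_now = ss.session.HR
            push(ss.end_time, _EV_EX_END, ss)
            if strategy.polls_during_exercise:
                tp = t
                while tp < ss.end_time - 1e-9:
                    push(tp, _EV_POLL, ss)
                    tp += _POLL_STEP
            cond = classify_insulin_condition([b.time for b in boluses], t)
            for off, grams in strategy.during_schedule(
                    ss.session.duration, cond):
                push(t + off, _EV_SNACK, (ss, grams))

        t = 0.0
        while heap:
            ev_t, kind, _, payload = heapq.heappop(heap)
            ev_t = min(ev_t, plan.horizon)
            integrate_to(t, ev_t)
            t = ev_t

            if kind == _EV_MEAL:
                active_meals.append(payload)

            elif kind == _EV_BOLUS:
                pb: PlannedBolus = payload
                red = strategy.bolus_reduction(t, plan.exercise)
                dose = compute_bolus(BolusRequest(
                    CHO=pb.carbs_g, G_current=y[IX_G], ICR=p.ICR, CF=p.CF,
                    Gt=p.Gt, reduction_fraction=red))
                y[IX_X1] += dose * MICROUNITS_PER_UNIT
                boluses.append(Bolus(time=t, dose=dose))
                if red > 0:
                    log.add(t, "bolus_reduction", red, y[IX_G], 0.0)

            elif kind == _EV_EX_START:
                ss = sess_states[id(payload)]
                ctx = context(t, ss)
                grams, delay = strategy.at_exercise_onset(ctx)
                ss.onset_done = True
                if grams > 0:
                    add_snack(t, grams, ctx.G, ctx.trend)
                if delay:
                    log.add(t, "exercise_delay", _POLL_STEP, ctx.G, ctx.trend)
                    push(t + _POLL_STEP, _EV_DELAY, ss)
                else:
                    start_session(t, ss)

            elif kind == _EV_DELAY:
                ss = payload
                if y[IX_G] > 90.0:
                    start_session(t, ss)
                elif t - ss.session.start >= _DELAY_CAP - 1e-9:
                    ss.cancelled = True
                    log.add(t, "exercise_cancelled", 0.0, y[IX_G], 0.0)
                else:
                    push(t + _POLL_STEP, _EV_DELAY, ss)

            elif kind == _EV_POLL:
                ss = payload
                if ss.running:
                    ctx = context(t, ss)
                    grams, suspend = strategy.poll(ctx)
                    if suspend:
                        ss.running = False
                        ss.suspended = True
                        hr_now = p.HRb
                        log.add(t, "exercise_suspended", 0.0, ctx.G,
                                ctx.trend)
                    elif grams > 0:
                        add_snack(t, grams, ctx.G, ctx.trend)

            elif kind == _EV_SNACK:
                ss, grams = payload
                if ss.running:
                    add_snack(t, grams, y[IX_G], 0.0)

            elif kind == _EV_EX_END:
                ss = payload
                if ss.running:
                    ss.running = False
                    hr_now = p.HRb
                    ctx = context(t, ss)
                    grams = strategy.at_exercise_end(ctx)
                    if grams > 0:
                        add_snack(t, grams, ctx.G, ctx.trend)

        integrate_to(t, plan.horizon)
        traj = Trajectory(time=grid, states=states, HR=hr_grid)
        return SimulationResult(trajectory=traj, log=log, boluses=boluses)


def simulate(plan: DayPlan, params: PatientParams | None = None,
             strategy: Strategy | None = None, *,
             output_step: float = 1.0, rtol: float = 1e-8,
             atol: float = 1e-10) -> SimulationResult:
    """Convenience wrapper: simulate one day plan and return the result."""
    sim = Simulator(params, rtol=rtol, atol=atol, output_step=output_step)
    return sim.run(plan, strategy)
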