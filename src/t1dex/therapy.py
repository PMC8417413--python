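"""Bolus calculation and meal/bolus scheduling for the standard day.

The bolus calculator mirrors multiple-daily-injection practice: the dose
covers the meal carbohydrates through the insulin-to-carbohydrate ratio and
corrects the current glucose towards the target through the correction
factor, and is rounded to the nearest 0.5 U.  No insulin-on-board correction
is applied (injections are well separated in all simulated days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import (Meal, ExerciseSession, TAU_MAX_MEAL, TAU_MAX_SNACK,
                     clock_to_minutes)

VALID_REDUCTIONS = (0.0, 0.25, 0.50, 0.75)


@dataclass(frozen=True)
class BolusRequest:
    """Inputs to the bolus calculator for one meal."""

    CHO: float                     # g of carbohydrate in the meal
    G_current: float               # mg/dl, simulated glucose at injection
    ICR: float                     # g/U
    CF: float                      # mg/dl per U
    Gt: float                      # mg/dl, target glucose
    reduction_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.CHO < 0:
            raise ValueError("CHO must be >= 0")
        if self.reduction_fraction not in VALID_REDUCTIONS:
            raise ValueError("reduction_fraction must be one of "
                             f"{VALID_REDUCTIONS}")


def round_to_half(dose: float) -> float:
    """Round a dose to the nearest 0.5 U; exact ties round up."""
    import math
    return math.floor(dose * 2.0 + 0.5) / 2.0


def compute_bolus(req: BolusRequest) -> float:
    """Meal bolus in U: (1 - reduction)·max(0, CHO/ICR + (G - Gt)/CF), rounded.

    The exercise-related reduction is applied multiplicatively to the raw
    dose before rounding; negative raw doses clamp to zero.
    """
    if req.ICR <= 0 or req.CF <= 0:
        raise ValueError("ICR and CF must be strictly positive")
    raw = req.CHO / req.ICR + (req.G_current - req.Gt) / req.CF
    raw = max(0.0, raw) * (1.0 - req.reduction_fraction)
    return round_to_half(raw)


@dataclass(frozen=True)
class PlannedBolus:
    """A bolus scheduled for a given time; the dose is computed at run time
    from the simulated glucose and the carbohydrates of the covered meal."""

    time: float        # min
    carbs_g: float     # g of the meal this bolus covers


@dataclass
class DayPlan:
    """All scheduled inputs for one simulated day.

    Strategy-triggered snacks are injected at run time and use
    ``snack_tau_max`` (fast-acting carbohydrates); ``extra_meals`` carries
    any pre-specified additional intake.
    """

    meals: list[Meal] = field(default_factory=list)
    boluses: list[PlannedBolus] = field(default_factory=list)
    exercise: list[ExerciseSession] = field(default_factory=list)
    extra_meals: list[Meal] = field(default_factory=list)
    horizon: float = 1440.0
    snack_tau_max: float = TAU_MAX_SNACK

    def validate(self) -> None:
        for m in list(self.meals) + list(self.extra_meals):
            if not 0 <= m.time <= self.horizon:
                raise ValueError(f"meal at t={m.time} outside horizon")
        for b in self.boluses:
            if not 0 <= b.time <= self.horizon:
                raise ValueError(f"bolus at t={b.time} outside horizon")
        sessions = sorted(self.exercise, key=lambda s: s.start)
        for s in sessions:
            if not 0 <= s.start <= self.horizon:
                raise ValueError(f"exercise at t={s.start} outside horizon")
        for a, b in zip(sessions, sessions[1:]):
            if a.end > b.start:
                raise ValueError("overlapping exercise sessions")

    def to_config(self) -> dict:
        """Structured-text representation (round-trips with from_config)."""
        return {
            "meals": [{"time": m.time, "carbs_g": m.carbs_mg / 1000.0,
                       "tau_max": m.tau_max, "f_bio": m.f_bio}
                      for m in self.meals],
            "boluses": [{"time": b.time, "carbs_g": b.carbs_g}
                        for b in self.boluses],
            "exercise": [{"start": s.start, "duration": s.duration,
                          "HR": s.HR} for s in self.exercise],
            "horizon": self.horizon,
            "snack_tau_max": self.snack_tau_max,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "DayPlan":
        known = {"meals", "boluses", "exercise", "horizon", "snack_tau_max"}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown day-plan keys: {sorted(unknown)}")
        return cls(
            meals=[Meal(time=m["time"], carbs_mg=m["carbs_g"] * 1000.0,
                        tau_max=m.get("tau_max", TAU_MAX_MEAL),
                        f_bio=m.get("f_bio", 0.8))
                   for m in cfg.get("meals", [])],
            boluses=[PlannedBolus(time=b["time"], carbs_g=b["carbs_g"])
                     for b in cfg.get("boluses", [])],
            exercise=[ExerciseSession(start=e["start"],
                                      duration=e["duration"], HR=e["HR"])
                      for e in cfg.get("exercise", [])],
            horizon=cfg.get("horizon", 1440.0),
            snack_tau_max=cfg.get("snack_tau_max", TAU_MAX_SNACK),
        )


BOLUS_LEAD_TIME = 15.0   # min before each meal

STANDARD_MEALS = (
    ("07:00", 50.0),   # breakfast
    ("13:00", 70.0),   # lunch
    ("19:00", 60.0),   # dinner
)


def standard_day(*, lunch_time: str | None = None,
                 f_bio: float = 0.8) -> DayPlan:
    """The reference day: 50 g at 07:00, 70 g at 13:00, 60 g at 19:00.

    All main meals use tau_max = 60 min (typical mixed meal).  A bolus is
    scheduled 15 min before each meal; its dose is computed at injection
    time from the simulated glucose.  ``lunch_time`` moves lunch (used by
    the postabsorptive-exercise scenario).
    """
    plan = DayPlan()
    for clock, grams in STANDARD_MEALS:
        if lunch_time is not None and clock == "13:00":
            clock = lunch_time
        t = clock_to_minutes(clock)
        plan.meals.append(Meal(time=t, carbs_mg=grams * 1000.0,
                               tau_max=TAU_MAX_MEAL, f_bio=f_bio))
        plan.boluses.append(PlannedBolus(time=t - BOLUS_LEAD_TIME,
                                         carbs_g=grams))
    return plan
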