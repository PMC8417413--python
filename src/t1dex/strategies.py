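"""Treatment-adjustment strategies for exercise days.

Three rule engines are provided:

* ``CHOAlgorithm`` — a CGM-trend carbohydrate-intake decision tree evaluated
  every 5 min during exercise: snacks of 8/16/20 g depending on the glucose
  level and its 5-min downward trend, with a 20-min minimum spacing between
  snacks, and suspension of exercise below 70 mg/dl.
* ``ConsensusStrategy`` — consensus-guideline adjustments: proportional
  meal-bolus reduction when the bolus falls within 120 min of exercise onset
  (by intensity and duration), carbohydrate intake at exercise onset by
  glucose level and insulin condition (with exercise delayed below
  90 mg/dl), hourly carbohydrate supplementation during exercise by duration
  bracket, and 20 g without bolus if glucose is below 90 mg/dl at session
  end.  The guidelines give ranges; ``variant`` selects the low or high end.
* ``NoAdjustment`` — the do-nothing baseline.

All snacks are fast-acting carbohydrates (tau_max = 20 min) and never
receive an insulin bolus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import ExerciseSession

#: a simulation is in the high insulin condition if any bolus was injected
#: at most this many minutes before exercise onset
HIGH_INSULIN_WINDOW = 120.0

#: minimum spacing between successive snacks of the CHO intake algorithm
MIN_SNACK_SPACING = 20.0


@dataclass(frozen=True)
class StrategyContext:
    """Snapshot handed to a strategy when it is consulted."""

    time: float                      # min since 06:00
    G: float                         # mg/dl, simulated glucose
    trend: float                     # mg/dl per 5 min (negative = dropping)
    session: ExerciseSession | None
    time_since_last_snack: float     # min, inf if no snack yet
    bolus_times: list                # times of realized boluses so far
    insulin_condition: str           # "low" | "high"


@dataclass(frozen=True)
class LogEntry:
    time: float
    action: str       # snack | bolus_reduction | exercise_delay | ...
    amount: float     # grams, fraction, or minutes depending on action
    trigger_G: float
    trigger_trend: float


@dataclass
class AdjustmentLog:
    """Chronological record of every strategy action taken in a run."""

    entries: list = field(default_factory=list)

    def add(self, time, action, amount, trigger_G, trigger_trend) -> None:
        self.entries.append(LogEntry(time, action, amount,
                                     trigger_G, trigger_trend))

    def snacks(self) -> list:
        return [e for e in self.entries if e.action == "snack"]

    def total_snack_grams(self) -> float:
        return sum(e.amount for e in self.snacks())

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(
            [(e.time, e.action, e.amount, e.trigger_G, e.trigger_trend)
             for e in self.entries],
            columns=["time", "action", "amount", "trigger_BG",
                     "trigger_trend"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def classify_insulin_condition(bolus_times, exercise_start) -> str:
    """'high' if any bolus was injected at most 120 min before exercise onset."""
    for bt in bolus_times:
        if 0.0 <= exercise_start - bt <= HIGH_INSULIN_WINDOW:
            return "high"
    return "low"


def cho_algorithm_step(ctx: StrategyContext) -> tuple[float, bool]:
    """One 5-min evaluation of the CGM-trend carbohydrate-intake algorithm.

    Returns (snack grams, suspend flag).  ``ctx.trend`` is the signed 5-min
    glucose change; the algorithm acts on the drop rate -trend.
    """
    g = ctx.G
    if g < 70.0:
        return 0.0, True
    drop = -ctx.trend
    grams = 0.0
    if g < 90.0:
        grams = 16.0
    elif g < 110.0:
        if drop > 9.9:
            grams = 20.0
        elif drop > 5.4:
            grams = 16.0
    elif g < 126.0:
        if drop > 5.4:
            grams = 8.0
    if grams > 0 and ctx.time_since_last_snack < MIN_SNACK_SPACING:
        grams = 0.0
    return grams, False


def consensus_bolus_reduction(HR: float, duration: float,
                              bolus_to_exercise_gap: float) -> float:
    """Fractional meal-bolus reduction for a pre-exercise bolus.

    Applies only when the bolus falls within 120 min of exercise onset.
    Brackets (heart rate right-open, duration closed at 60 min):
    HR 100-130: 25% (duration <= 60) / 50% (> 60); HR 130-155: 50% / 75%;
    HR >= 155: 75% either way.  Below HR 100 the table does not apply.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not 0.0 <= bolus_to_exercise_gap <= HIGH_INSULIN_WINDOW:
        return 0.0
    short = duration <= 60.0
    if HR < 100.0:
        return 0.0
    if HR < 130.0:
        return 0.25 if short else 0.50
    if HR < 155.0:
        return 0.50 if short else 0.75
    return 0.75


def consensus_onset_action(G: float, condition: str) -> tuple[float, bool]:
    """Carbohydrates at exercise onset and whether to delay the start.

    Below 90 mg/dl: 15 g (low insulin condition) / 25 g (high) and the
    session is postponed until glucose exceeds 90 mg/dl; 90-124 mg/dl: 10 g;
    above 124 mg/dl: nothing.
    """
    if G < 90.0:
        return (25.0 if condition == "high" else 15.0), True
    if G <= 124.0:
        return 10.0, False
    return 0.0, False


# during-exercise carbohydrate recommendations: (low condition, high condition)
# entries are g/h except the <=30 min high-condition row, which is a total.
_DURING_RATES = {
    "short": {"low": (0.0, 0.0), "high": (15.0, 30.0)},    # <=30 min, total g
    "mid": {"low": (10.0, 15.0), "high": (30.0, 60.0)},    # 30-60 min, g/h
    "long": {"low": (30.0, 60.0), "high": (60.0, 70.0)},   # >60 min, g/h
}


def consensus_during_total(duration: float, condition: str,
                           variant: str) -> float:
    """Total during-exercise carbohydrates [g] for a session."""
    idx = 0 if variant == "low" else 1
    if duration <= 30.0:
        return _DURING_RATES["short"][condition][idx]
    bracket = "mid" if duration <= 60.0 else "long"
    rate = _DURING_RATES[bracket][condition][idx]   # g/h
    return rate * duration / 60.0


def consensus_during_schedule(duration: float, condition: str,
                              variant: str) -> list[tuple[float, float]]:
    """Discretize the during-exercise intake into (offset, grams) portions.

    The total is split into equal portions every 30 min starting 30 min
    after exercise onset; a session shorter than 30 min receives its total
    at session end.
    """
    total = consensus_during_total(duration, condition, variant)
    if total <= 0:
        return []
    n_portions = int(duration // 30.0)
    if n_portions == 0:
        return [(duration, total)]
    portion = total / n_portions
    return [(30.0 * (i + 1), portion) for i in range(n_portions)]


def consensus_end_action(G: float) -> float:
    """20 g without bolus if glucose is below 90 mg/dl at session end."""
    return 20.0 if G < 90.0 else 0.0


@dataclass(frozen=True)
class ConsensusPlan:
    """Resolved consensus-guideline actions for one session."""

    onset_grams: float
    delay_start: bool                  # postpone until glucose > 90 mg/dl
    during: tuple                      # (offset min, grams) portions
    end_grams_if_low: float = 20.0     # applied when BG < 90 at session end


def consensus_cho_plan(ctx: StrategyContext, variant: str) -> ConsensusPlan:
    """Full carbohydrate plan for the session in ``ctx``.

    Combines the onset rule (by glucose and insulin condition), the
    during-exercise supplementation schedule (by duration bracket and the
    chosen end of the recommended range) and the end-of-session rule.
    """
    if ctx.session is None:
        raise ValueError("context carries no exercise session")
    grams, delay = consensus_onset_action(ctx.G, ctx.insulin_condition)
    during = consensus_during_schedule(ctx.session.duration,
                                       ctx.insulin_condition, variant)
    return ConsensusPlan(onset_grams=grams, delay_start=delay,
                         during=tuple(during))


class Strategy:
    """Base class: the no-adjustment contract every strategy refines."""

    name = "none"
    polls_during_exercise = False

    def bolus_reduction(self, bolus_time: float, sessions) -> float:
        return 0.0

    def at_exercise_onset(self, ctx: StrategyContext) -> tuple[float, bool]:
        return 0.0, False

    def poll(self, ctx: StrategyContext) -> tuple[float, bool]:
        return 0.0, False

    def during_schedule(self, duration: float, condition: str) -> list:
        return []

    def at_exercise_end(self, ctx: StrategyContext) -> float:
        return 0.0


class NoAdjustment(Strategy):
    """Baseline: the day plan is executed with no exercise-related changes."""


class CHOAlgorithm(Strategy):
    """CGM-trend carbohydrate-intake decision tree, polled every 5 min."""

    name = "cho_algorithm"
    polls_during_exercise = True

    def poll(self, ctx: StrategyContext) -> tuple[float, bool]:
        return cho_algorithm_step(ctx)


class ConsensusStrategy(Strategy):
    """Consensus-guideline adjustments; ``variant`` picks the low or high
    end of each recommended carbohydrate range."""

    polls_during_exercise = False

    def __init__(self, variant: str):
        if variant not in ("low", "high"):
            raise ValueError("variant must be 'low' or 'high'")
        self.variant = variant
        self.name = f"consensus_{variant}"

    def bolus_reduction(self, bolus_time: float, sessions) -> float:
        for s in sessions:
            red = consensus_bolus_reduction(s.HR, s.duration,
                                            s.start - bolus_time)
            if red > 0:
                return red
        return 0.0

    def at_exercise_onset(self, ctx: StrategyContext) -> tuple[float, bool]:
        return consensus_onset_action(ctx.G, ctx.insulin_condition)

    def during_schedule(self, duration: float, condition: str) -> list:
        return consensus_during_schedule(duration, condition, self.variant)

    def at_exercise_end(self, ctx: StrategyContext) -> float:
        return consensus_end_action(ctx.G)


STRATEGY_NAMES = ("none", "cho_algorithm", "consensus_low", "consensus_high")


def get_strategy(name: str) -> Strategy:
    """Look up a strategy by its config name."""
    if name == "none":
        return NoAdjustment()
    if name == "cho_algorithm":
        return CHOAlgorithm()
    if name == "consensus_low":
        return ConsensusStrategy("low")
    if name == "consensus_high":
        return ConsensusStrategy("high")
    raise ValueError(f"unknown strategy {name!r}; "
                     f"expected one of {STRATEGY_NAMES}")
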