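"""Patient parameters and day-plan event types.

The physiological constants describe a single 'typical' adult with type 1
diabetes: a minimal-model glucose-insulin core, an exercise extension driven
by over-basal heart rate, a gamma-shaped meal appearance model and a
two-compartment subcutaneous insulin kinetics model.  Therapy constants
(insulin-to-carbohydrate ratio, correction factor, target glucose) describe
the person's bolus calculator settings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields


@dataclass(frozen=True)
class PatientParams:
    """Physiological and therapy constants for one virtual subject.

    Units follow the conventions of the minimal-model literature:
    glucose in mg/dl, insulin concentration in µU/ml, heart rate in bpm,
    time in minutes.
    """

    # glucose-insulin regulation
    p1: float = 0.0041       # 1/min, glucose effectiveness
    p2: float = 0.0155       # 1/min, remote insulin action decay
    p3: float = 6.913e-6     # 1/min^2 per µU/ml, insulin sensitivity
    Gb: float = 172.0        # mg/dl, basal (untreated) plasma glucose
    alpha: float = 2.59e-4   # dimensionless, exercise-driven insulin-sensitivity gain
    beta: float = 3.39e-4    # 1/bpm, insulin-independent exercise glucose clearance
    tauHR: float = 5.0       # min, heart-rate response time constant
    tau: float = 600.0       # min, decay time of post-exercise sensitivity elevation
    a: float = 0.1           # dimensionless, exercise-onset fraction of basal HR
    n: float = 4.0           # dimensionless, Hill exponent of the onset switch
    # meal appearance
    f_bio: float = 0.8       # dimensionless, meal bioavailability
    Vg: float = 1.6          # dl/kg, glucose distribution volume
    # subcutaneous insulin kinetics
    k21: float = 0.0085      # 1/min
    kd: float = 0.0247       # 1/min
    ka: float = 0.011        # 1/min
    ke: float = 0.0357       # 1/min
    Vi: float = 104.0        # ml/kg, insulin distribution volume
    # subject & therapy constants
    BW: float = 70.0         # kg, body weight
    HRb: float = 80.0        # bpm, resting heart rate
    Ib: float = 10.0         # µU/ml, basal insulin concentration
    Gt: float = 120.0        # mg/dl, target glucose
    ICR: float = 15.0        # g/U, insulin-to-carbohydrate ratio
    CF: float = 20.0         # mg/dl per U, correction factor

    def __post_init__(self) -> None:
        positive = ("p1", "p2", "p3", "Gb", "tauHR", "tau", "f_bio", "Vg",
                    "k21", "kd", "ka", "ke", "Vi", "BW", "HRb", "ICR", "CF")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.f_bio <= 1:
            raise ValueError("f_bio must lie in (0, 1]")
        if not 0 < self.a < 1:
            raise ValueError("a must lie in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.Gb > self.Gt > 0:
            raise ValueError("require Gb > Gt > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")

    def replace(self, **changes) -> "PatientParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: time of maximum appearance for a slow mixed meal [min]
TAU_MAX_MEAL = 60.0
#: time of maximum appearance for fast-acting exercise snacks [min]
TAU_MAX_SNACK = 20.0


@dataclass(frozen=True)
class Meal:
    """Carbohydrate intake event.  ``carbs_mg`` is the ingested amount D in mg."""

    time: float              # min since simulation start (06:00)
    carbs_mg: float          # mg
    tau_max: float = TAU_MAX_MEAL
    f_bio: float = 0.8

    def __post_init__(self) -> None:
        if self.carbs_mg < 0:
            raise ValueError("carbs_mg must be >= 0")
        if self.tau_max <= 0:
            raise ValueError("tau_max must be > 0")


@dataclass(frozen=True)
class Bolus:
    """A realized insulin bolus: dose in U, multiple of 0.5."""

    time: float              # min
    dose: float              # U

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if abs(self.dose * 2 - round(self.dose * 2)) > 1e-9:
            raise ValueError("dose must be a multiple of 0.5 U")


@dataclass(frozen=True)
class ExerciseSession:
    """One continuous moderate-intensity exercise bout at constant heart rate."""

    start: float             # min
    duration: float          # min
    HR: float                # bpm, must exceed the resting heart rate

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


def clock_to_minutes(clock: str) -> float:
    """Convert an 'HH:MM' wall-clock time to minutes since the 06:00 start.

    Times before 06:00 are interpreted as the following night (e.g. '02:00'
    maps to 1200 min).
    """
    hh, mm = clock.split(":")
    m = int(hh) * 60 + int(mm) - 360
    if m < 0:
        m += 1440
    return float(m)


def minutes_to_clock(minutes: float) -> str:
    """Inverse of :func:`clock_to_minutes` (wraps past midnight)."""
    total = (int(round(minutes)) + 360) % 1440
    return f"{total // 60:02d}:{total % 60:02d}"
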