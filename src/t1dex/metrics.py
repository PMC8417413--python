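"""Glycemic performance measures: TIR, the BG risk function, LBGI/HBGI.

The blood-glucose risk function maps a glucose reading onto a symmetric
risk scale, r(G) = 10·1.5092·[(ln G)^1.084 - 5.381]^2, with its minimum at
112.5 mg/dl.  Readings below (above) the minimum define the low (high)
blood-glucose index as the average of the clipped risk over *all* readings.
Time-in-range is the fraction of readings inside 70-180 mg/dl.

All indices are computed on a 5-min subsample of the simulated trajectory,
mirroring CGM readings; glucose is clamped to the risk function's standard
domain [20, 600] mg/dl before risk evaluation (TIR uses unclamped values).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

RISK_MINIMUM_BG = 112.5     # mg/dl, argmin of the risk function
BG_CLAMP = (20.0, 600.0)    # mg/dl, domain of the risk function
TIR_RANGE = (70.0, 180.0)   # mg/dl, desired glucose range
METRIC_STEP = 5.0           # min, CGM-like sampling step for all indices

_C1 = 10.0 * 1.5092
_EXP = 1.084
_OFF = 5.381


def risk(G):
    """BG risk r(G) >= 0; input clamped to [20, 600] mg/dl."""
    g = np.clip(np.asarray(G, dtype=float), *BG_CLAMP)
    val = _C1 * (np.log(g) ** _EXP - _OFF) ** 2
    return float(val) if np.isscalar(G) else val


def risk_low(G):
    """Risk attributed to low readings: r(G) for G < 112.5 mg/dl, else 0."""
    g = np.asarray(G, dtype=float)
    out = np.where(g < RISK_MINIMUM_BG, risk(g), 0.0)
    return float(out) if np.isscalar(G) else out


def risk_high(G):
    """Risk attributed to high readings: r(G) for G >= 112.5 mg/dl, else 0."""
    g = np.asarray(G, dtype=float)
    out = np.where(g >= RISK_MINIMUM_BG, risk(g), 0.0)
    return float(out) if np.isscalar(G) else out


def _check(trace) -> np.ndarray:
    arr = np.asarray(trace, dtype=float)
    if arr.size == 0:
        raise ValueError("empty glucose trace")
    return arr


def lbgi(trace) -> float:
    """Low blood-glucose index: mean of risk_low over all readings."""
    return float(np.mean(risk_low(_check(trace))))


def hbgi(trace) -> float:
    """High blood-glucose index: mean of risk_high over all readings."""
    return float(np.mean(risk_high(_check(trace))))


def tir(trace) -> float:
    """Time-in-range [%]: share of readings with 70 <= G <= 180 mg/dl."""
    arr = _check(trace)
    lo, hi = TIR_RANGE
    return float(np.mean((arr >= lo) & (arr <= hi)) * 100.0)


def subsample(time, G, step: float = METRIC_STEP):
    """CGM-like readings: samples at multiples of ``step`` minutes."""
    time = np.asarray(time, dtype=float)
    G = _check(G)
    mask = np.isclose(time % step, 0.0) | np.isclose(time % step, step)
    out = G[mask]
    if out.size == 0:
        raise ValueError(f"no samples on the {step}-min metric grid")
    return out


def windowed_lbgi(time, G, window) -> float:
    """LBGI restricted to readings with t0 <= t <= t1."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty metric window")
    time = np.asarray(time, dtype=float)
    G = _check(G)
    mask = (time >= t0) & (time <= t1)
    if not mask.any():
        raise ValueError("window contains no samples")
    return lbgi(subsample(time[mask] - t0, G[mask]))


@dataclass(frozen=True)
class MetricsReport:
    """Summary of one simulated day."""

    TIR_24h: float
    LBGI_24h: float
    HBGI_24h: float
    LBGI_acute: float      # during exercise and up to 60 min after
    LBGI_late: float       # overnight, 19:00-06:00
    acute_window: tuple
    late_window: tuple

    def to_dict(self) -> dict:
        d = asdict(self)
        d["acute_window"] = list(self.acute_window)
        d["late_window"] = list(self.late_window)
        return d


LATE_WINDOW = (780.0, 1440.0)   # 19:00h to 06:00h next morning
ACUTE_TAIL = 60.0               # min after exercise end


def metrics_report(trajectory, exercise=None) -> MetricsReport:
    """Compute the full metric panel for a simulated trajectory.

    ``exercise`` (an ExerciseSession, or None) fixes the acute-hypoglycemia
    window as [session start, session end + 60 min].
    """
    t = trajectory.time
    g = trajectory.G
    readings = subsample(t, g)
    if exercise is not None:
        acute = (exercise.start, min(exercise.end + ACUTE_TAIL, t[-1]))
        lbgi_acute = windowed_lbgi(t, g, acute)
    else:
        acute = (0.0, 0.0)
        lbgi_acute = 0.0
    return MetricsReport(
        TIR_24h=tir(readings),
        LBGI_24h=lbgi(readings),
        HBGI_24h=hbgi(readings),
        LBGI_acute=lbgi_acute,
        LBGI_late=windowed_lbgi(t, g, LATE_WINDOW),
        acute_window=acute,
        late_window=LATE_WINDOW,
    )
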