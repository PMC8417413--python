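import numpy as np
import pytest

import t1dex as tx


@pytest.fixture(scope="session")
def params():
    return tx.PatientParams()


@pytest.fixture(scope="session")
def standard_plan():
    return tx.standard_day()


def exercise_day(start, duration=60.0, HR=120.0, lunch_time=None):
    plan = tx.standard_day(lunch_time=lunch_time)
    plan.exercise.append(tx.ExerciseSession(start=start, duration=duration,
                                            HR=HR))
    return plan


@pytest.fixture(scope="session")
def standard_day_result(params):
    """Standard day, no exercise, reference solver."""
    return tx.simulate(tx.standard_day(), params)


@pytest.fixture(scope="session")
def headline_result(params):
    """Standard day + 60 min at 120 bpm starting 15:00h, no adjustment."""
    return tx.simulate(exercise_day(540.0), params)


def g_between(result, t0, t1):
    t = result.trajectory.time
    g = result.trajectory.G
    return g[(t >= t0) & (t <= t1)]
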