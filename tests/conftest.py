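import numpy as np
import pytest

from gazeddm.gaze import Fixation, TrialRecord
from gazeddm.task import ChoiceProblem, Option
from gazeddm.synth import generate_problems


@pytest.fixture(scope="session")
def problem_battery():
    """60 analyzable safe-vs-risky problems, half risky.better."""
    return generate_problems(60, rng=12345, p_risky_better=0.5)


def make_trial(problem, fixations, choice, rt_ms, pid="s000", tid="t000"):
    return TrialRecord(
        participant_id=pid,
        trial_id=tid,
        problem=problem,
        fixations=fixations,
        choice=choice,
        rt_ms=rt_ms,
    )


@pytest.fixture()
def exclusion_fixture():
    """20 trials: 3 on equal-EV problems, 2 on safe-safe problems, 2 with
    only off-AOI fixations, 13 clean -> the filters must keep exactly 13."""
    normal = [
        ChoiceProblem(f"norm{i}", Option.safe(10 + i), Option.risky(40 + i, 0.5))
        for i in range(15)
    ]
    equal_ev = [
        ChoiceProblem(f"eq{i}", Option.safe(20), Option.risky(40, 0.5)) for i in range(3)
    ]
    safe_safe = [
        ChoiceProblem(f"ss{i}", Option.safe(5), Option.safe(15)) for i in range(2)
    ]
    aoi_fix = [Fixation("option_a", 300.0, 0.0), Fixation("option_b", 200.0, 300.0)]
    none_fix = [Fixation("none", 400.0, 0.0)]
    trials = []
    k = 0
    for p in normal[:13]:
        trials.append(make_trial(p, list(aoi_fix), "option_a", 1500.0, tid=f"t{k:03d}"))
        k += 1
    for p in equal_ev:
        trials.append(make_trial(p, list(aoi_fix), "option_a", 1500.0, tid=f"t{k:03d}"))
        k += 1
    for p in safe_safe:
        trials.append(make_trial(p, list(aoi_fix), "option_b", 1500.0, tid=f"t{k:03d}"))
        k += 1
    for p in normal[13:15]:
        trials.append(make_trial(p, list(none_fix), "option_a", 1500.0, tid=f"t{k:03d}"))
        k += 1
    assert len(trials) == 20
    return trials
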