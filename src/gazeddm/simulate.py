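"""Forward simulation of the attentional drift-diffusion model (aDDM).

Evidence for each option accumulates in 1-ms steps. While option A is
attended, DV_A gains d*V_A and DV_B gains d*theta*V_B per step (and vice
versa while B is attended); each accumulator also receives an independent
N(0, sigma) noise sample per step. A choice is made once the relative
decision variable RDV = DV_A - DV_B satisfies |RDV| >= alpha/2: option A at
the upper boundary (RDV > 0), option B at the lower. Response time is the
number of accumulation steps plus the non-decision time t0.

Because the difference of two independent Gaussian increments is itself
Gaussian, the simulator integrates RDV directly with per-step mean
d*(V_att - theta*V_unatt) (signed) and noise SD sigma*sqrt(2); this is
distributionally identical to simulating the two accumulators separately
and much cheaper.

The fixation process is an explicit, configurable part of the simulation
(the estimation procedure, by contrast, conditions on observed fixations):
by default the first fixation lands on either option with equal probability,
fixations then alternate, and dwell durations are drawn from a discretized
Gamma distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .gaze import Fixation, compute_gaze_proportions
from .task import ChoiceProblem, expected_value

__all__ = [
    "ADDMGenerativeParams",
    "FixationProcess",
    "ReplayFixations",
    "SimulatedTrial",
    "TruncationError",
    "simulate_trial",
    "simulate_experiment",
    "psychometric_summary",
]

DT_MS = 1  # accumulation time step


class TruncationError(RuntimeError):
    """Accumulation did not terminate within max_steps."""


@dataclass(frozen=True)
class ADDMGenerativeParams:
    """Generative aDDM parameters on the simulator's ms/value scale.

    d      evidence scaling per ms per value unit (> 0)
    theta  distortion factor for the unattended option (>= 0; 1 = none)
    sigma  per-accumulator noise SD per ms step (> 0)
    alpha  boundary separation on the RDV scale (> 0); threshold is alpha/2
    t0     non-decision time in ms (>= 0)
    """

    d: float
    theta: float
    sigma: float
    alpha: float
    t0: float

    def __post_init__(self):
        if self.d <= 0 or self.sigma <= 0 or self.alpha <= 0:
            raise ValueError("d, sigma, alpha must be > 0")
        if self.t0 < 0 or self.theta < 0:
            raise ValueError("t0 and theta must be >= 0")


@dataclass(frozen=True)
class FixationProcess:
    """Generates an unbounded alternating fixation sequence on demand.

    first_fixation_p_a   probability the first fixation lands on option A
    dwell_shape          Gamma shape of dwell durations
    dwell_mean_a/b       mean dwell (ms) when fixating option A / B;
                         distinct means implement dwell bias
    """

    first_fixation_p_a: float = 0.5
    dwell_shape: float = 2.0
    dwell_mean_a: float = 400.0
    dwell_mean_b: float = 400.0

    def __post_init__(self):
        if not 0 <= self.first_fixation_p_a <= 1:
            raise ValueError("first_fixation_p_a must be in [0,1]")
        if min(self.dwell_shape, self.dwell_mean_a, self.dwell_mean_b) <= 0:
            raise ValueError("dwell parameters must be > 0")

    def first(self, rng: np.random.Generator) -> str:
        return "option_a" if rng.random() < self.first_fixation_p_a else "option_b"

    def dwell(self, aoi: str, rng: np.random.Generator) -> int:
        mean = self.dwell_mean_a if aoi == "option_a" else self.dwell_mean_b
        # discretized Gamma, at least one step
        return max(1, int(round(rng.gamma(self.dwell_shape, mean / self.dwell_shape))))

    def sequence(self, rng: np.random.Generator):
        aoi = self.first(rng)
        while True:
            yield aoi, self.dwell(aoi, rng)
            aoi = "option_b" if aoi == "option_a" else "option_a"


class ReplayFixations:
    """Fixation process that replays an observed sequence.

    After the sequence is exhausted it continues by alternating with the
    mean observed dwell, so simulation never starves.
    """

    def __init__(self, fixations: Sequence[Fixation]):
        usable = [f for f in fixations if f.aoi in ("option_a", "option_b")]
        if not usable:
            raise ValueError("need at least one option fixation to replay")
        self._fixations = usable
        self._mean_dwell = max(1, int(round(np.mean([f.duration for f in usable]))))

    def sequence(self, rng: np.random.Generator):
        last = None
        for f in self._fixations:
            last = f.aoi
            yield f.aoi, max(1, int(round(f.duration)))
        while True:
            last = "option_b" if last == "option_a" else "option_a"
            yield last, self._mean_dwell


@dataclass
class SimulatedTrial:
    choice: str
    rt: float  # ms, t0 + accumulation steps
    fixations: list[Fixation]
    rdv: np.ndarray | None = field(default=None, repr=False)
    problem_id: str | None = None
    rep: int | None = None


def _step_means(params: ADDMGenerativeParams, v_a: float, v_b: float) -> dict[str, float]:
    """Mean per-step RDV increment while each option is attended."""
    return {
        "option_a": params.d * (v_a - params.theta * v_b),
        "option_b": params.d * (params.theta * v_a - v_b),
    }


def simulate_trial(
    params: ADDMGenerativeParams,
    problem: ChoiceProblem,
    fix: FixationProcess | ReplayFixations | None = None,
    rng: np.random.Generator | int | None = None,
    max_steps: int = 20_000,
    record_trajectory: bool = False,
) -> SimulatedTrial:
    """Simulate one trial; raises :class:`TruncationError` past ``max_steps``."""
    if fix is None:
        fix = FixationProcess()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    v_a = expected_value(problem.option_a)
    v_b = expected_value(problem.option_b)
    means = _step_means(params, v_a, v_b)
    sigma_eff = params.sigma * math.sqrt(2.0)
    threshold = params.alpha / 2.0

    rdv = 0.0
    steps = 0
    fixations: list[Fixation] = []
    traj: list[np.ndarray] = []
    for aoi, dwell in fix.sequence(rng):
        n = min(dwell, max_steps - steps)
        if n <= 0:
            raise TruncationError(
                f"trial on problem {problem.id} not terminated after {max_steps} steps "
                f"(|RDV|={abs(rdv):.3g} < {threshold:.3g})"
            )
        noise = rng.standard_normal(n) * sigma_eff if sigma_eff > 0 else np.zeros(n)
        path = rdv + np.cumsum(means[aoi] + noise)
        if record_trajectory:
            traj.append(path)
        hit = np.abs(path) >= threshold
        if hit.any():
            k = int(np.argmax(hit))  # first crossing step within this dwell
            fixations.append(Fixation(aoi=aoi, duration=float(k + 1), onset=float(steps)))
            steps += k + 1
            final = path[k]
            choice = "option_a" if final > 0 else "option_b"
            rdv_series = None
            if record_trajectory:
                traj[-1] = path[: k + 1]
                rdv_series = np.concatenate(traj)
            return SimulatedTrial(
                choice=choice,
                rt=params.t0 + steps,
                fixations=fixations,
                rdv=rdv_series,
                problem_id=problem.id,
            )
        fixations.append(Fixation(aoi=aoi, duration=float(n), onset=float(steps)))
        steps += n
        rdv = float(path[-1])
        if steps >= max_steps:
            raise TruncationError(
                f"trial on problem {problem.id} not terminated after {max_steps} steps "
                f"(|RDV|={abs(rdv):.3g} < {threshold:.3g})"
            )


def simulate_experiment(
    params: ADDMGenerativeParams,
    problems: Sequence[ChoiceProblem],
    fix: FixationProcess | None = None,
    n_reps: int = 1,
    seed: int | np.random.SeedSequence | None = None,
    max_steps: int = 20_000,
) -> list[SimulatedTrial]:
    """Independent trials over problems x reps, reproducible from ``seed``."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(problems) * n_reps)
    out = []
    i = 0
    for rep in range(n_reps):
        for problem in problems:
            trial = simulate_trial(
                params, problem, fix, np.random.default_rng(children[i]), max_steps
            )
            trial.rep = rep
            out.append(trial)
            i += 1
    return out


def psychometric_summary(
    trials: Sequence[SimulatedTrial],
    problems: Sequence[ChoiceProblem],
    n_bins: int = 5,
) -> pd.DataFrame:
    """P(choose higher-EV) and mean RT by |EV difference| bin."""
    by_id = {p.id: p for p in problems}
    rows = []
    for t in trials:
        p = by_id[t.problem_id]
        ev_a, ev_b = expected_value(p.option_a), expected_value(p.option_b)
        if abs(ev_a - ev_b) <= 1e-9:
            continue
        higher = "option_a" if ev_a > ev_b else "option_b"
        rows.append(
            {
                "ev_gap": abs(ev_a - ev_b),
                "chose_higher_ev": float(t.choice == higher),
                "rt": t.rt,
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return pd.DataFrame(columns=["ev_gap_bin", "p_higher_ev", "mean_rt", "n"])
    frame["ev_gap_bin"] = pd.cut(frame["ev_gap"], bins=n_bins)
    grouped = frame.groupby("ev_gap_bin", observed=True)
    out = grouped.agg(
        p_higher_ev=("chose_higher_ev", "mean"),
        mean_rt=("rt", "mean"),
        n=("chose_higher_ev", "size"),
    ).reset_index()
    return out


def trial_gaze_consistency(trial: SimulatedTrial) -> float:
    """Gaze proportion on option A recomputed from the recorded fixations."""
    return compute_gaze_proportions(trial.fixations).gaze_a
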