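"""Synthetic risky-choice eye-tracking experiments.

Generates complete cohorts — numeracy scores, safe-vs-risky choice
problems, numeracy-linked generative aDDM parameters, fixation sequences,
choices and response times — with the statistical structure the analysis
pipeline assumes, so that every stage (gaze preprocessing, Wiener-likelihood
fitting, mediation GLMs) can be exercised without any external data.

Emulated design: 80 participants x 100 binary choices between a safe option
(one outcome, p = 1) and a risky option (one non-zero outcome, else 0);
non-zero outcomes are integers in [1, 95]; roughly 49% of problems are
risky.better. Numeracy scores follow a discretized Normal(3.7, 1.6)
truncated to 0..7. The distortion factor theta and boundary separation
alpha (and, optionally, a dwell bias toward the higher-EV option) are
linear functions of z-standardized numeracy with problem-type-specific
slopes and between-participant noise — so decision quality is linked to
numeracy *only* through the generative aDDM parameters and the attention
bias, never through a direct path.

Generative parameters are specified on the Wiener-likelihood scale
(unit-noise diffusion, seconds) and converted to simulator units via
`gazeddm.wfpt.likelihood_to_sim_units`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze import Fixation, TrialRecord, compute_gaze_proportions
from .simulate import ADDMGenerativeParams, FixationProcess, TruncationError, simulate_trial
from .task import ChoiceProblem, Option, ProblemType, classify_problem, problems_to_frame
from .wfpt import likelihood_to_sim_units

__all__ = [
    "LinearLink",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_numeracy",
    "generate_problems",
    "link_parameters",
    "generate_dataset",
]

_P_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


@dataclass(frozen=True)
class LinearLink:
    """intercept + slope_by_type * z(numeracy) + Normal(0, sd) per participant."""

    intercept: float
    slope_rb: float
    slope_sb: float
    sd: float
    type_offset_sb: float = 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Parameter-link defaults were calibrated once (scripts in examples/) so
    that cohort-level numeracy-parameter correlations fall in a plausible
    0.2-0.6 band and fitted mediator-model coefficients land at the order of
    magnitude observed empirically for this task class.
    """

    n_participants: int = 80
    n_problems: int = 100
    seed: int = 0
    # numeracy distribution: discretized truncated normal on 0..7
    numeracy_mean: float = 3.7
    numeracy_sd: float = 1.6
    # problem construction
    p_risky_better: float = 0.49
    equal_ev_rate: float = 0.0
    safe_safe_rate: float = 0.0
    # generative links on the likelihood scale
    theta_link: LinearLink = field(
        default_factory=lambda: LinearLink(intercept=0.44, slope_rb=0.09, slope_sb=0.03, sd=0.18)
    )
    log_alpha_link: LinearLink = field(
        default_factory=lambda: LinearLink(
            intercept=float(np.log(3.2)), slope_rb=0.05, slope_sb=0.05, sd=0.20, type_offset_sb=0.09
        )
    )
    # target gaze share on the higher-EV option (dwell bias); sd across participants
    attention_link: LinearLink = field(
        default_factory=lambda: LinearLink(intercept=0.543, slope_rb=0.012, slope_sb=-0.018, sd=0.04)
    )
    beta0: float = 0.0
    beta1_median: float = 0.06
    beta1_log_sd: float = 0.15
    t0_s: float = 0.35
    t0_log_sd: float = 0.15
    sigma: float = 0.05  # simulator per-accumulator noise SD per ms step
    dwell_shape: float = 2.0
    dwell_total_mean_ms: float = 800.0  # mean_H + mean_L; split by the gaze target
    first_fixation_p_higher: float = 0.5
    max_steps: int = 30_000
    theta_clip: tuple[float, float] = (0.0, 1.3)
    attention_clip: tuple[float, float] = (0.2, 0.8)


@dataclass
class SyntheticDataset:
    problems: list[ChoiceProblem]
    participants: pd.DataFrame  # numeracy + true generative parameters
    trials: pd.DataFrame  # participant_id, trial_id, problem_id, choice, rt_ms
    fixations: pd.DataFrame  # long format
    config: SyntheticConfig
    n_truncation_retries: int = 0

    def trial_records(self) -> list[TrialRecord]:
        from .gaze import assemble_trials

        return assemble_trials(self.trials, self.fixations, self.problems)

    def analysis_trial_table(self) -> pd.DataFrame:
        """Trial-level table (problem type, decision quality, attention)."""
        by_id = {p.id: p for p in self.problems}
        fix_groups = dict(tuple(self.fixations.groupby(["participant_id", "trial_id"])))
        rows = []
        for _, t in self.trials.iterrows():
            problem = by_id[t["problem_id"]]
            ptype = classify_problem(problem)
            key = (t["participant_id"], t["trial_id"])
            fixes = [
                Fixation(aoi=r["aoi"], duration=r["duration_ms"], onset=r["onset_ms"])
                for _, r in fix_groups[key].iterrows()
            ]
            gaze = compute_gaze_proportions(fixes)
            higher = problem.higher_ev_option()
            rows.append(
                {
                    "participant_id": t["participant_id"],
                    "trial_id": t["trial_id"],
                    "problem_type": ptype,
                    "chose_higher_ev": float(t["choice"] == higher),
                    "attention": gaze.gaze_on(higher),
                    "rt_ms": t["rt_ms"],
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir, hide_truth: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        problems_to_frame(self.problems).to_csv(out / "problems.csv", index=False)
        participants = self.participants
        if hide_truth:
            participants = participants[["participant_id", "numeracy"]]
        participants.to_csv(out / "participants.csv", index=False)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.fixations.to_csv(out / "fixations.csv", index=False)


def generate_numeracy(
    n: int,
    rng: np.random.Generator | int | None = None,
    mean: float = 3.7,
    sd: float = 1.6,
    dist: np.ndarray | None = None,
) -> np.ndarray:
    """Integer numeracy scores in 0..7.

    Default distribution: Normal(mean, sd) probability mass at each integer
    0..7 (renormalized), matching the reported sample mean/median; ``dist``
    overrides with explicit probabilities.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n == 0:
        return np.array([], dtype=int)
    if dist is None:
        from scipy.stats import norm

        grid = np.arange(8)
        dist = norm.pdf(grid, loc=mean, scale=sd)
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (8,) or (dist < 0).any() or dist.sum() <= 0:
        raise ValueError("dist must be 8 non-negative weights over scores 0..7")
    return rng.choice(8, size=n, p=dist / dist.sum())


def _draw_problem(rng: np.random.Generator, want_type: str, idx: int) -> ChoiceProblem:
    for _ in range(1000):
        x_s = int(rng.integers(2, 61))
        x_r = int(rng.integers(x_s + 5, 96))
        evs = _P_GRID * x_r
        if want_type == ProblemType.RISKY_BETTER:
            valid = _P_GRID[evs > x_s + 1e-9]
        else:
            valid = _P_GRID[evs < x_s - 1e-9]
        if valid.size:
            p = float(rng.choice(valid))
            return ChoiceProblem(
                id=f"p{idx:04d}",
                option_a=Option.safe(x_s),
                option_b=Option.risky(x_r, p),
                layout={"safe_side": "left" if rng.random() < 0.5 else "right"},
            )
    raise RuntimeError("could not construct a problem of the requested type")


def generate_problems(
    n: int,
    rng: np.random.Generator | int | None = None,
    p_risky_better: float = 0.49,
    equal_ev_rate: float = 0.0,
    safe_safe_rate: float = 0.0,
) -> list[ChoiceProblem]:
    """Safe-vs-risky problems with integer outcomes in [1, 95].

    Probabilities come from a 0.05 grid (emulating experienced relative
    frequencies under a yoked design). Each problem is risky.better with
    probability ``p_risky_better``. Equal-EV and safe-safe problems are only
    emitted when their injection rates are set (for exercising the filters).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    problems = []
    for i in range(n):
        u = rng.random()
        if u < equal_ev_rate:
            x_s = int(rng.integers(1, 48))  # x_r = 2*x_s <= 95
            problems.append(
                ChoiceProblem(
                    id=f"p{i:04d}",
                    option_a=Option.safe(x_s),
                    option_b=Option.risky(2 * x_s, 0.5),
                )
            )
        elif u < equal_ev_rate + safe_safe_rate:
            x1 = int(rng.integers(1, 90))
            x2 = int(rng.integers(x1 + 1, 96))
            problems.append(
                ChoiceProblem(
                    id=f"p{i:04d}", option_a=Option.safe(x1), option_b=Option.safe(x2)
                )
            )
        else:
            want = (
                ProblemType.RISKY_BETTER
                if rng.random() < p_risky_better
                else ProblemType.SAFE_BETTER
            )
            problems.append(_draw_problem(rng, want, i))
    return problems


def link_parameters(
    numeracy: np.ndarray,
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-participant true generative parameters by problem type.

    theta is a clipped linear function of z(numeracy); alpha is log-normal
    with a log-linear numeracy effect; the attention target (gaze share on
    the higher-EV option) a clipped linear function. Clipping counts are
    recorded in the frame's ``attrs``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    numeracy = np.asarray(numeracy, dtype=float)
    n = len(numeracy)
    sd = numeracy.std(ddof=1)
    z = (numeracy - numeracy.mean()) / sd if sd > 0 else np.zeros(n)

    def linear(link: LinearLink, slope_attr: str, offset: float = 0.0) -> np.ndarray:
        slope = getattr(link, slope_attr)
        return link.intercept + offset + slope * z + rng.normal(0, link.sd, size=n)

    th = config.theta_link
    theta_rb = linear(th, "slope_rb")
    theta_sb = linear(th, "slope_sb")
    lo, hi = config.theta_clip
    n_clipped = int(np.sum((theta_rb < lo) | (theta_rb > hi) | (theta_sb < lo) | (theta_sb > hi)))
    theta_rb, theta_sb = np.clip(theta_rb, lo, hi), np.clip(theta_sb, lo, hi)

    la = config.log_alpha_link
    alpha_rb = np.exp(linear(la, "slope_rb"))
    alpha_sb = np.exp(linear(la, "slope_sb", offset=la.type_offset_sb))

    at = config.attention_link
    attn_rb = np.clip(linear(at, "slope_rb"), *config.attention_clip)
    attn_sb = np.clip(linear(at, "slope_sb"), *config.attention_clip)

    beta1 = config.beta1_median * np.exp(rng.normal(0, config.beta1_log_sd, size=n))
    t0_s = config.t0_s * np.exp(rng.normal(0, config.t0_log_sd, size=n))

    frame = pd.DataFrame(
        {
            "participant_id": [f"s{i:03d}" for i in range(n)],
            "numeracy": numeracy.astype(int),
            "theta_rb": theta_rb,
            "theta_sb": theta_sb,
            "alpha_rb": alpha_rb,
            "alpha_sb": alpha_sb,
            "attention_target_rb": attn_rb,
            "attention_target_sb": attn_sb,
            "beta0": config.beta0,
            "beta1": beta1,
            "t0_s": t0_s,
        }
    )
    frame.attrs["n_theta_clipped"] = n_clipped
    return frame


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic experiment, reproducible from config.seed."""
    config = config or SyntheticConfig()
    ss = np.random.SeedSequence(config.seed)
    ss_problems, ss_numeracy, ss_params, ss_trials = ss.spawn(4)

    problems = generate_problems(
        config.n_problems,
        np.random.default_rng(ss_problems),
        p_risky_better=config.p_risky_better,
        equal_ev_rate=config.equal_ev_rate,
        safe_safe_rate=config.safe_safe_rate,
    )
    numeracy = generate_numeracy(
        config.n_participants,
        np.random.default_rng(ss_numeracy),
        mean=config.numeracy_mean,
        sd=config.numeracy_sd,
    )
    participants = link_parameters(numeracy, config, np.random.default_rng(ss_params))

    analyzable = [
        p
        for p in problems
        if classify_problem(p) in (ProblemType.RISKY_BETTER, ProblemType.SAFE_BETTER)
    ]
    trial_rows = []
    fixation_rows = []
    n_retries = 0
    trial_seeds = ss_trials.spawn(config.n_participants)
    for i, prow in participants.iterrows():
        pid = prow["participant_id"]
        rng_p = np.random.default_rng(trial_seeds[i])
        for j, problem in enumerate(analyzable):
            ptype = classify_problem(problem)
            suffix = "rb" if ptype == ProblemType.RISKY_BETTER else "sb"
            d, alpha_sim, t0_ms = likelihood_to_sim_units(
                prow["beta1"],
                prow[f"alpha_{suffix}"],
                prow["t0_s"],
                config.sigma,
            )
            params = ADDMGenerativeParams(
                d=d,
                theta=prow[f"theta_{suffix}"],
                sigma=config.sigma,
                alpha=alpha_sim,
                t0=t0_ms,
            )
            higher = problem.higher_ev_option()
            r = prow[f"attention_target_{suffix}"]
            mean_h = config.dwell_total_mean_ms * r
            mean_l = config.dwell_total_mean_ms * (1.0 - r)
            p_first_a = (
                config.first_fixation_p_higher
                if higher == "option_a"
                else 1.0 - config.first_fixation_p_higher
            )
            fix = FixationProcess(
                first_fixation_p_a=p_first_a,
                dwell_shape=config.dwell_shape,
                dwell_mean_a=mean_h if higher == "option_a" else mean_l,
                dwell_mean_b=mean_h if higher == "option_b" else mean_l,
            )
            trial = None
            for _ in range(10):
                try:
                    trial = simulate_trial(params, problem, fix, rng_p, max_steps=config.max_steps)
                    break
                except TruncationError:
                    n_retries += 1
            if trial is None:
                raise TruncationError(
                    f"participant {pid}, problem {problem.id}: repeated non-termination"
                )
            trial_id = f"t{j:04d}"
            trial_rows.append(
                {
                    "participant_id": pid,
                    "trial_id": trial_id,
                    "problem_id": problem.id,
                    "choice": trial.choice,
                    "rt_ms": trial.rt,
                }
            )
            for f in trial.fixations:
                fixation_rows.append(
                    {
                        "participant_id": pid,
                        "trial_id": trial_id,
                        "aoi": f.aoi,
                        "onset_ms": f.onset,
                        "duration_ms": f.duration,
                    }
                )

    return SyntheticDataset(
        problems=problems,
        participants=participants,
        trials=pd.DataFrame(trial_rows),
        fixations=pd.DataFrame(fixation_rows),
        config=config,
        n_truncation_retries=n_retries,
    )
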