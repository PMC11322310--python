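"""Per-participant Bayesian estimation of the attentional DDM.

Each participant's trials are modelled jointly with the Wiener first-passage
likelihood (`gazeddm.wfpt`): free parameters are the drift coefficients
(beta0, beta1) shared across problem types, beta2 split by problem type
(risky.better vs safe.better), boundary separation alpha split by problem
type, and non-decision time t0. The distortion factor theta = beta2/beta1 is
derived per posterior draw, separately per problem type. Numeracy never
enters the fit; it is related to the fitted parameters only downstream, in
the mediation analyses.

Sampling uses differential-evolution Metropolis (`gazeddm._demc`): a
population of interacting chains whose difference-vector proposals adapt
automatically to the posterior's scale and correlation. Convergence is
monitored with the split-R-hat potential scale reduction factor.

Priors (weakly informative, on the likelihood scale):
    beta0, beta1, beta2 ~ Normal(0, 5)
    alpha               ~ Gamma(shape 2, rate 1), truncated to alpha > 0.1
    t0                  ~ Uniform(0, min observed RT - 1 ms)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from ._demc import run_demc
from .gaze import TrialRecord, filter_trials
from .task import ProblemType, classify_problem, expected_value
from .wfpt import MS_PER_S, _wfpt_logdensity_arr

__all__ = [
    "FitConfig",
    "ParticipantFit",
    "LowDataWarning",
    "fit_participant",
    "compute_rhat",
    "posterior_predict",
    "fit_cohort",
]

PARAM_NAMES = ["beta0", "beta1", "beta2_rb", "beta2_sb", "alpha_rb", "alpha_sb", "t0"]
DERIVED_NAMES = ["theta_rb", "theta_sb"]

_ALPHA_FLOOR = 0.1
_RHAT_FLAG = 1.01
_THETA_QC_BAND = (-0.25, 1.5)


class LowDataWarning(UserWarning):
    """Fewer analyzable trials than the recommended minimum."""


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings. Defaults are desk-scale; publication-scale runs
    (e.g. 30 chains x 10,000 draws with 5,000 burn-in) are a config away."""

    n_chains: int = 12
    n_samples: int = 8000  # total steps per chain, including burn-in
    n_burnin: int = 4000
    seed: int | None = None
    prior_beta_sd: float = 5.0
    max_init_attempts: int = 200

    def __post_init__(self):
        if self.n_chains < 4:
            raise ValueError("need at least 4 chains (population sampler + R-hat)")
        if not self.n_samples > self.n_burnin >= 0:
            raise ValueError("need n_samples > n_burnin >= 0")


@dataclass
class ParticipantFit:
    participant_id: str
    summary: pd.DataFrame  # index: parameter; columns: mean, sd, q2.5, q97.5, rhat
    draws: dict[str, np.ndarray]  # (n_chains, n_kept) per parameter (incl. derived)
    loglik: np.ndarray  # (n_chains, n_kept) total data log likelihood per draw
    n_trials: int
    accept_rate: float
    metadata: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool((self.summary["rhat"] <= _RHAT_FLAG).all())

    def posterior_mean(self, name: str) -> float:
        return float(self.summary.loc[name, "mean"])


# ---------------------------------------------------------------------------
# Trial data preparation


@dataclass(frozen=True)
class _TrialArrays:
    rt_s: np.ndarray
    chose_upper: np.ndarray  # bool: chose the higher-EV option
    gaze_higher: np.ndarray
    v_higher: np.ndarray
    v_lower: np.ndarray
    is_rb: np.ndarray  # bool: risky.better problem


def _prepare(trials: Sequence[TrialRecord]) -> _TrialArrays:
    rt, chose, g_hi, v_hi, v_lo, is_rb = [], [], [], [], [], []
    for t in trials:
        ptype = classify_problem(t.problem)
        higher = t.problem.higher_ev_option()
        gaze = t.ensure_gaze()
        ev_a = expected_value(t.problem.option_a)
        ev_b = expected_value(t.problem.option_b)
        if higher == "option_a":
            v_hi.append(ev_a), v_lo.append(ev_b), g_hi.append(gaze.gaze_a)
        else:
            v_hi.append(ev_b), v_lo.append(ev_a), g_hi.append(gaze.gaze_b)
        rt.append(t.rt_ms / MS_PER_S)
        chose.append(t.choice == higher)
        is_rb.append(ptype == ProblemType.RISKY_BETTER)
    return _TrialArrays(
        rt_s=np.asarray(rt),
        chose_upper=np.asarray(chose, bool),
        gaze_higher=np.asarray(g_hi),
        v_higher=np.asarray(v_hi),
        v_lower=np.asarray(v_lo),
        is_rb=np.asarray(is_rb, bool),
    )


def _loglik_population(theta: np.ndarray, data: _TrialArrays) -> np.ndarray:
    """Summed trial log likelihood for an (n_chains, 7) parameter matrix."""
    b0 = theta[:, 0:1]
    b1 = theta[:, 1:2]
    b2 = np.where(data.is_rb[None, :], theta[:, 2:3], theta[:, 3:4])
    a = np.where(data.is_rb[None, :], theta[:, 4:5], theta[:, 5:6])
    t0 = theta[:, 6:7]
    g_hi = data.gaze_higher[None, :]
    g_lo = 1.0 - g_hi
    x1 = g_hi * data.v_higher[None, :] - g_lo * data.v_lower[None, :]
    x2 = g_lo * data.v_higher[None, :] - g_hi * data.v_lower[None, :]
    v = b0 + b1 * x1 + b2 * x2
    # observed-boundary density: upper(v) = lower(-v) at relative start 0.5
    v_signed = np.where(data.chose_upper[None, :], -v, v)
    ll = _wfpt_logdensity_arr(data.rt_s[None, :], "lower", v_signed, a, t0)
    return ll.sum(axis=1)


def _log_prior(theta: np.ndarray, rt_max_t0: float, prior_beta_sd: float) -> np.ndarray:
    betas = theta[:, 0:4]
    alphas = theta[:, 4:6]
    t0 = theta[:, 6]
    lp = -0.5 * np.sum(betas**2, axis=1) / prior_beta_sd**2
    ok = (alphas > _ALPHA_FLOOR).all(axis=1) & (t0 > 0) & (t0 < rt_max_t0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = lp + np.where(ok, np.sum(np.log(np.maximum(alphas, 1e-300)) - alphas, axis=1), -np.inf)
    return lp


def _init_population(
    rng: np.random.Generator, n_chains: int, rt_min: float, log_post, max_attempts: int
) -> np.ndarray:
    """Draw a finite-posterior starting population, re-jittering as needed."""
    center = np.array([0.0, 0.05, 0.025, 0.025, 2.5, 2.5, 0.5 * rt_min])
    scale = np.array([0.02, 0.02, 0.01, 0.01, 0.5, 0.5, 0.15 * rt_min])
    pop = np.empty((n_chains, 7))
    filled = 0
    for _ in range(max_attempts):
        cand = center + scale * rng.standard_normal((n_chains, 7))
        cand[:, 4:6] = np.abs(cand[:, 4:6]) + _ALPHA_FLOOR
        cand[:, 6] = np.clip(cand[:, 6], 1e-3, rt_min - 2e-3)
        finite = np.isfinite(log_post(cand))
        take = min(int(finite.sum()), n_chains - filled)
        pop[filled : filled + take] = cand[finite][:take]
        filled += take
        if filled == n_chains:
            return pop
    raise RuntimeError("could not find a finite-posterior starting population")


def fit_participant(
    trials: Sequence[TrialRecord],
    config: FitConfig | None = None,
    participant_id: str | None = None,
) -> ParticipantFit:
    """MCMC posterior for one participant's aDDM parameters.

    All parameters are estimated jointly in a single step from the
    participant's analyzable trials; theta is computed from beta2/beta1 per
    draw and then summarized.
    """
    config = config or FitConfig()
    kept, _ = filter_trials(list(trials))
    if not kept:
        raise ValueError("no analyzable trials")
    pid = participant_id or kept[0].participant_id
    data = _prepare(kept)
    if len(kept) < 20 or data.is_rb.all() or (~data.is_rb).all():
        warnings.warn(
            f"participant {pid}: {len(kept)} analyzable trials "
            f"({int(data.is_rb.sum())} risky.better); estimates may be unstable",
            LowDataWarning,
            stacklevel=2,
        )
    rt_min = float(data.rt_s.min())
    t0_upper = rt_min - 1e-3

    def log_post(theta: np.ndarray) -> np.ndarray:
        lp = _log_prior(theta, t0_upper, config.prior_beta_sd)
        ok = np.isfinite(lp)
        if ok.any():
            lp[ok] = lp[ok] + _loglik_population(theta[ok], data)
        return lp

    rng = np.random.default_rng(config.seed)
    init = _init_population(rng, config.n_chains, rt_min, log_post, config.max_init_attempts)
    res = run_demc(log_post, init, config.n_samples, config.n_burnin, rng)

    draws = {name: res.draws[:, :, i] for i, name in enumerate(PARAM_NAMES)}
    draws["theta_rb"] = draws["beta2_rb"] / draws["beta1"]
    draws["theta_sb"] = draws["beta2_sb"] / draws["beta1"]
    loglik = res.logpost - _log_prior(
        res.draws.reshape(-1, 7), t0_upper, config.prior_beta_sd
    ).reshape(res.logpost.shape)

    rows = []
    for name in PARAM_NAMES + DERIVED_NAMES:
        d = draws[name]
        rows.append(
            {
                "parameter": name,
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)),
                "q2.5": float(np.quantile(d, 0.025)),
                "q97.5": float(np.quantile(d, 0.975)),
                "rhat": float(az.rhat(az.convert_to_dataset(d))["x"].values.item()),
            }
        )
    summary = pd.DataFrame(rows).set_index("parameter")

    theta_qc = {}
    for name in DERIVED_NAMES:
        lo, hi = summary.loc[name, "q2.5"], summary.loc[name, "q97.5"]
        theta_qc[name] = bool(lo < _THETA_QC_BAND[0] or hi > _THETA_QC_BAND[1])

    return ParticipantFit(
        participant_id=pid,
        summary=summary,
        draws=draws,
        loglik=loglik,
        n_trials=len(kept),
        accept_rate=res.accept_rate,
        metadata={
            "upper_boundary": "higher_ev_option",
            "drift_orientation": "Eq-style drift with the higher-EV option in the B role",
            "theta_interval_qc_flag": theta_qc,
            "n_risky_better": int(data.is_rb.sum()),
            "config": config,
        },
    )


def compute_rhat(chains: np.ndarray | dict[str, np.ndarray]) -> pd.Series:
    """Split-R-hat per parameter from (n_chains, n_draws) arrays."""
    if isinstance(chains, np.ndarray):
        chains = {"x": chains}
    out = {}
    for name, arr in chains.items():
        arr = np.asarray(arr, float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("R-hat needs >= 2 chains of equal length")
        out[name] = float(az.rhat(az.convert_to_dataset(arr))["x"].values.item())
    return pd.Series(out, name="rhat")


def posterior_predict(
    fit: ParticipantFit,
    trials: Sequence[TrialRecord],
    mode: str = "modal",
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Posterior predictive choices at the posterior-mean parameters.

    ``modal`` predicts the choice with probability > 0.5 on every trial;
    ``sample`` draws a choice from the predictive probability. Returns the
    per-trial predictive probability of choosing the higher-EV option, the
    predicted choices, and the fraction matching the empirical choices.
    """
    if mode not in ("modal", "sample"):
        raise ValueError("mode must be 'modal' or 'sample'")
    kept, _ = filter_trials(list(trials))
    data = _prepare(kept)
    theta = np.array([[fit.posterior_mean(n) for n in PARAM_NAMES]])
    b0, b1 = theta[0, 0], theta[0, 1]
    b2 = np.where(data.is_rb, theta[0, 2], theta[0, 3])
    a = np.where(data.is_rb, theta[0, 4], theta[0, 5])
    g_hi = data.gaze_higher
    g_lo = 1.0 - g_hi
    v = (
        b0
        + b1 * (g_hi * data.v_higher - g_lo * data.v_lower)
        + b2 * (g_lo * data.v_higher - g_hi * data.v_lower)
    )
    p_upper = expit(v * a)
    if mode == "modal":
        pred_upper = p_upper > 0.5
    else:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        pred_upper = rng.random(p_upper.shape) < p_upper
    match = pred_upper == data.chose_upper
    return {
        "p_choose_higher_ev": p_upper,
        "predicted_chose_higher_ev": pred_upper,
        "match_rate": float(match.mean()),
        "n_trials": len(kept),
    }


def fit_cohort(
    trials: Sequence[TrialRecord],
    config: FitConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, ParticipantFit]]:
    """Fit every participant; returns a tidy (participant, problem_type)
    table of posterior means plus the full fits.

    Individual fit failures are recorded (NaN rows) and the cohort continues.
    """
    config = config or FitConfig()
    by_pid: dict[str, list[TrialRecord]] = {}
    for t in trials:
        by_pid.setdefault(t.participant_id, []).append(t)

    rows = []
    fits: dict[str, ParticipantFit] = {}
    base_seed = config.seed if config.seed is not None else 0
    for i, (pid, ptrials) in enumerate(sorted(by_pid.items())):
        pconfig = FitConfig(
            n_chains=config.n_chains,
            n_samples=config.n_samples,
            n_burnin=config.n_burnin,
            seed=(base_seed + 1000003 * (i + 1)) % (2**31),
            prior_beta_sd=config.prior_beta_sd,
            max_init_attempts=config.max_init_attempts,
        )
        try:
            fit = fit_participant(ptrials, pconfig, participant_id=pid)
        except Exception as exc:  # keep going; record the failure
            warnings.warn(f"fit failed for participant {pid}: {exc}", stacklevel=2)
            for ptype in (ProblemType.RISKY_BETTER, ProblemType.SAFE_BETTER):
                rows.append(
                    {
                        "participant_id": pid,
                        "problem_type": ptype,
                        "theta_hat": np.nan,
                        "alpha_hat": np.nan,
                        "beta0_hat": np.nan,
                        "beta1_hat": np.nan,
                        "t0_hat": np.nan,
                        "rhat_max": np.nan,
                        "n_trials": len(ptrials),
                        "fit_ok": False,
                    }
                )
            continue
        fits[pid] = fit
        for ptype, suffix in (
            (ProblemType.RISKY_BETTER, "rb"),
            (ProblemType.SAFE_BETTER, "sb"),
        ):
            rows.append(
                {
                    "participant_id": pid,
                    "problem_type": ptype,
                    "theta_hat": fit.posterior_mean(f"theta_{suffix}"),
                    "alpha_hat": fit.posterior_mean(f"alpha_{suffix}"),
                    "beta0_hat": fit.posterior_mean("beta0"),
                    "beta1_hat": fit.posterior_mean("beta1"),
                    "t0_hat": fit.posterior_mean("t0"),
                    "rhat_max": float(fit.summary["rhat"].max()),
                    "n_trials": fit.n_trials,
                    "fit_ok": True,
                }
            )
    return pd.DataFrame(rows), fits
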