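"""Wiener first-passage-time likelihood with gaze-weighted trial drifts.

The attentional DDM is estimated by treating each trial as a constant-drift
Wiener diffusion between two absorbing boundaries, with the trial's drift
built from the options' expected values and the observed gaze proportions:

    delta = beta0 + beta1*(gaze_B*V_B - gaze_A*V_A)
                  + beta2*(gaze_A*V_B - gaze_B*V_A)

where beta1 is the aDDM's value-scaling constant d (up to the documented
noise/time rescaling), beta2 the scaling applied to the momentarily
unattended option, and theta = beta2/beta1 the distortion factor. The drift
formula is oriented with option "B" at the upper boundary: averaging the
aDDM's per-step increments of RDV = DV_A - DV_B over a trial with gaze
shares (gaze_A, gaze_B) gives a mean drift toward B equal to the two value
terms above. Because estimation maps the *upper* boundary to the higher-EV
option, the trial likelihood relabels options so that B is the higher-EV
option; beta0 is then a drift bias toward the higher-EV option.

All densities use unit diffusion coefficient and time in seconds; the
relative starting point is fixed at 0.5 (equidistant boundaries).

Unit conversion from the millisecond-step simulator (`gazeddm.simulate`):
with per-step value drift d*V, per-accumulator noise SD sigma (so RDV noise
SD sigma_eff = sigma*sqrt(2) per 1-ms step),

    drift (1/s, unit noise):      beta1 = d * sqrt(1000) / sigma_eff
    boundary separation:          a     = alpha_sim / (sigma_eff * sqrt(1000))
    non-decision time:            t0_s  = t0_ms / 1000
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gaze import TrialGaze, TrialRecord
from .task import classify_problem, expected_value

__all__ = [
    "DriftCoefficients",
    "WienerTrialParams",
    "trial_drift",
    "theta_from_coeffs",
    "wfpt_logdensity",
    "choice_probability",
    "trial_loglik",
    "sim_to_likelihood_units",
    "likelihood_to_sim_units",
]

MS_PER_S = 1000.0


@dataclass(frozen=True)
class DriftCoefficients:
    beta0: float
    beta1: float
    beta2: float


@dataclass(frozen=True)
class WienerTrialParams:
    """Constant-drift Wiener parameters; relative start fixed at 0.5."""

    drift: float
    alpha: float  # boundary separation, > 0
    t0: float  # non-decision time, seconds, >= 0
    rel_start: float = 0.5

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if self.rel_start != 0.5:
            raise ValueError("relative starting point is fixed at 0.5")


def trial_drift(
    coeffs: DriftCoefficients,
    gaze: TrialGaze,
    values: tuple[float, float],
) -> float:
    """Gaze-weighted drift toward option B's boundary.

    ``values`` are the two options' expected values (V_A, V_B).
    """
    v_a, v_b = values
    g_a, g_b = gaze.gaze_a, gaze.gaze_b
    return (
        coeffs.beta0
        + coeffs.beta1 * (g_b * v_b - g_a * v_a)
        + coeffs.beta2 * (g_a * v_b - g_b * v_a)
    )


def theta_from_coeffs(coeffs: DriftCoefficients) -> float:
    """Distortion factor theta = beta2 / beta1."""
    if coeffs.beta1 == 0:
        raise ZeroDivisionError("theta undefined: beta1 = 0")
    return coeffs.beta2 / coeffs.beta1


# ---------------------------------------------------------------------------
# First-passage-time density.
#
# For unit diffusion, boundaries at 0 and a, start w*a, drift v, the density
# of absorption at the LOWER boundary at decision time t is
#
#   f_lower(t) = a^-2 * exp(-v*a*w - v^2 t / 2) * f1(t / a^2, w)
#
# where f1 is the zero-drift unit-boundary density, computed with either the
# small-time or the large-time series; the expansion is chosen per element by
# comparing the number of terms each needs for a target truncation error
# (Navarro & Bogacz-style bound), capped at _KMAX terms.

_TT_SWITCH = 0.35  # scaled-time threshold between small- and large-time series
_K_SMALL = np.arange(-3, 4, dtype=float)  # 7 terms: truncation error < 1e-10 at tt <= 0.35
_K_LARGE = np.arange(1, 8, dtype=float)  # 7 terms: truncation error < 1e-10 at tt >= 0.35


def _f1(tt: np.ndarray, w: float) -> np.ndarray:
    """Zero-drift, unit-boundary FPT density at scaled time tt, start w.

    Small-time (image-sum) and large-time (eigenfunction) series, switched
    at a fixed scaled time where both are converged well beyond the term
    counts used.
    """
    tt = np.asarray(tt, dtype=float)
    out = np.zeros_like(tt)
    pos = tt > 0
    if not np.any(pos):
        return out
    t = tt[pos]
    val = np.empty_like(t)
    small = t <= _TT_SWITCH
    if small.any():
        ts = t[small, None]
        wk = w + 2.0 * _K_SMALL[None, :]
        val[small] = np.sum(wk * np.exp(-(wk**2) / (2.0 * ts)), axis=1) / np.sqrt(
            2.0 * np.pi * t[small] ** 3
        )
    if (~small).any():
        tl = t[~small, None]
        val[~small] = np.pi * np.sum(
            _K_LARGE * np.exp(-(_K_LARGE**2) * np.pi**2 * tl / 2.0) * np.sin(_K_LARGE * np.pi * w),
            axis=1,
        )
    out[pos] = np.maximum(val, 0.0)
    return out


def wfpt_logdensity(t, boundary: str, params: WienerTrialParams) -> np.ndarray | float:
    """Log FPT density at observed time(s) ``t`` for the given boundary.

    ``t`` is the full response time including t0; times at or below t0 get
    -inf (zero density), not an exception.
    """
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = _wfpt_logdensity_arr(
        t, boundary, np.asarray(params.drift), np.asarray(params.alpha), np.asarray(params.t0)
    )
    return float(out[0]) if scalar else out


def _wfpt_logdensity_arr(t, boundary: str, drift, alpha, t0, w: float = 0.5) -> np.ndarray:
    """Vectorized log density; drift/alpha/t0 broadcast against t."""
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    t, drift, alpha, t0 = np.broadcast_arrays(
        np.asarray(t, float), np.asarray(drift, float), np.asarray(alpha, float), np.asarray(t0, float)
    )
    td = t - t0
    if boundary == "upper":
        v_eff = -drift
        w_eff = 1.0 - w
    else:
        v_eff = drift
        w_eff = w
    out = np.full(t.shape, -np.inf)
    ok = td > 0
    if np.any(ok):
        tt = td[ok] / alpha[ok] ** 2
        # w is a scalar here (fixed 0.5 start); _f1 takes a scalar w
        f1 = _f1(tt, w_eff)
        with np.errstate(divide="ignore"):
            out[ok] = (
                np.log(f1)
                - 2.0 * np.log(alpha[ok])
                - v_eff[ok] * alpha[ok] * w_eff
                - v_eff[ok] ** 2 * td[ok] / 2.0
            )
    return out


def choice_probability(params: WienerTrialParams) -> float:
    """Probability of absorption at the upper boundary.

    With relative start 0.5 this is the logistic 1/(1 + exp(-drift*alpha)).
    """
    x = params.drift * params.alpha
    # logistic, numerically safe
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def trial_loglik(
    trial: TrialRecord,
    coeffs: DriftCoefficients,
    alpha: float,
    t0: float,
) -> float:
    """Log likelihood of one trial's (choice, RT) under the Wiener model.

    The upper boundary corresponds to the higher-EV option, so options are
    relabelled per trial such that "B" in the drift formula is the higher-EV
    option. RT at or below t0 contributes -inf.
    """
    classify_problem(trial.problem)  # raises nothing; ensures EVs computable
    higher = trial.problem.higher_ev_option()
    gaze = trial.ensure_gaze()
    ev_a = expected_value(trial.problem.option_a)
    ev_b = expected_value(trial.problem.option_b)
    if higher == "option_b":
        v_lo, v_hi = ev_a, ev_b
        g_hi = gaze.gaze_b
    else:
        v_lo, v_hi = ev_b, ev_a
        g_hi = gaze.gaze_a
    drift = drift_toward_higher_ev(coeffs, g_hi, v_hi, v_lo)
    params = WienerTrialParams(drift=drift, alpha=alpha, t0=t0)
    boundary = "upper" if trial.choice == higher else "lower"
    return float(wfpt_logdensity(trial.rt_ms / MS_PER_S, boundary, params))


def drift_toward_higher_ev(
    coeffs: DriftCoefficients, gaze_higher: float, v_higher, v_lower
) -> float | np.ndarray:
    """Drift toward the upper boundary (higher-EV option).

    Vectorized over gaze/value arrays; applies the drift formula with the
    higher-EV option in the "B" role.
    """
    g_hi = gaze_higher
    g_lo = 1.0 - g_hi
    return (
        coeffs.beta0
        + coeffs.beta1 * (g_hi * v_higher - g_lo * v_lower)
        + coeffs.beta2 * (g_lo * v_higher - g_hi * v_lower)
    )


# ---------------------------------------------------------------------------
# Unit conversions between the ms-step simulator and the likelihood scale.


def sim_to_likelihood_units(d: float, sigma: float, alpha_sim: float, t0_ms: float):
    """Map simulator parameters to Wiener-likelihood units.

    The simulator adds independent N(0, sigma) noise to each accumulator per
    1-ms step, so the relative decision variable has per-step noise SD
    sigma*sqrt(2); the likelihood uses unit diffusion and seconds.
    Returns (beta1, a, t0_s).
    """
    sigma_eff = sigma * math.sqrt(2.0)
    beta1 = d * math.sqrt(MS_PER_S) / sigma_eff
    a = alpha_sim / (sigma_eff * math.sqrt(MS_PER_S))
    return beta1, a, t0_ms / MS_PER_S


def likelihood_to_sim_units(beta1: float, a: float, t0_s: float, sigma: float):
    """Inverse of :func:`sim_to_likelihood_units` given the simulator sigma."""
    sigma_eff = sigma * math.sqrt(2.0)
    d = beta1 * sigma_eff / math.sqrt(MS_PER_S)
    alpha_sim = a * sigma_eff * math.sqrt(MS_PER_S)
    return d, alpha_sim, t0_s * MS_PER_S
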