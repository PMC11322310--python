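"""Bayesian mediation analyses linking numeracy to decision quality.

The statistical back end mirrors a three-model mediation scheme built from
Bayesian generalized linear models:

* Total Effect Model (TEM): logistic regression of choosing the higher-EV
  option on z-standardized numeracy.
* Mediator Models (MM): Gaussian regressions of each process-level measure
  (attention allocation, boundary separation alpha, distortion theta) on
  numeracy x problem type with a participant random intercept;
  ``risky.better`` is the reference level.
* Direct Effect Models (DEM): the TEM augmented with one or more
  process-level measures; mediation is summarized by how much the numeracy
  coefficient shrinks from TEM to DEM.

All slope coefficients carry zero-centered Normal(0, 1) priors (the
intercept a wider Normal(0, 5)); an effect is "credible" when its two-sided
95% posterior interval excludes zero. Posteriors are computed by MAP +
Laplace approximation (logistic) or in closed form conditional on
REML-estimated variance components (Gaussian, random intercepts) — both are
deterministic and accurate at the sample sizes involved; posterior draws
from the resulting Gaussian feed PSIS-LOO model comparison (loo-IC) via
arviz. Continuous predictors are z-standardized within each analyzed
subset. No multiple-comparison correction is applied; the shrinkage priors
are the only regularization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "GLMFit",
    "z_standardize",
    "fit_bayesian_glm",
    "total_effect_model",
    "mediator_model",
    "direct_effect_model",
    "mediation_summary",
    "vif",
    "loo_compare",
    "build_analysis_table",
]

MEASURES = ("attention", "alpha", "theta")
_MEASURE_COL = {"attention": "attention", "alpha": "alpha_hat", "theta": "theta_hat"}
SUBSETS = ("all", "risky.better", "safe.better")


def z_standardize(values, ddof: int = 1) -> np.ndarray:
    """Center to mean 0 and scale to SD 1 (sample SD by default)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-standardize a constant column")
    return (x - x.mean()) / sd


@dataclass
class GLMFit:
    family: str
    coef: pd.DataFrame  # index: term; columns mean, q2.5, q97.5, credible
    draws: np.ndarray  # (n_draws, p) posterior coefficient draws
    loglik_pointwise: np.ndarray  # (n_draws, n)
    n_obs: int
    outcome: np.ndarray
    terms: list[str]
    extra: dict = field(default_factory=dict)
    _loo_ic: float | None = field(default=None, repr=False)

    @property
    def loo_ic(self) -> float:
        # PSIS-LOO is the expensive part; computed on first use
        if self._loo_ic is None:
            self._loo_ic = _loo_ic(self.loglik_pointwise)
        return self._loo_ic

    def coefficient(self, term: str) -> pd.Series:
        return self.coef.loc[term]


def _coef_table(draws: np.ndarray, terms: list[str]) -> pd.DataFrame:
    mean = draws.mean(axis=0)
    lo = np.quantile(draws, 0.025, axis=0)
    hi = np.quantile(draws, 0.975, axis=0)
    return pd.DataFrame(
        {
            "mean": mean,
            "q2.5": lo,
            "q97.5": hi,
            "credible": (lo > 0) | (hi < 0),
        },
        index=pd.Index(terms, name="term"),
    )


def _loo_ic(loglik_pointwise: np.ndarray) -> float:
    idata = az.from_dict(
        posterior={"beta": loglik_pointwise[None, :, 0:1] * 0.0},
        log_likelihood={"y": loglik_pointwise[None]},
    )
    with np.errstate(all="ignore"):
        res = az.loo(idata, pointwise=False)
    return float(-2.0 * res.elpd_loo)


def _prior_precision(p: int, prior_sd: float, intercept_prior_sd: float) -> np.ndarray:
    prec = np.full(p, 1.0 / prior_sd**2)
    prec[0] = 1.0 / intercept_prior_sd**2
    return np.diag(prec)


def _newton_logistic(X, y, prior_prec, offset=None, max_iter=50, tol=1e-10):
    beta = np.zeros(X.shape[1])
    off = 0.0 if offset is None else offset
    for _ in range(max_iter):
        eta = X @ beta + off
        p = expit(eta)
        g = X.T @ (y - p) - prior_prec @ beta
        w = np.maximum(p * (1 - p), 1e-10)
        H = (X.T * w) @ X + prior_prec
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta + off
    p = expit(eta)
    w = np.maximum(p * (1 - p), 1e-10)
    H = (X.T * w) @ X + prior_prec
    return beta, H


def fit_bayesian_glm(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    family: str,
    group: str | None = None,
    prior_sd: float = 1.0,
    intercept_prior_sd: float = 5.0,
    n_draws: int = 1000,
    seed: int = 0,
) -> GLMFit:
    """Bayesian GLM with N(0, prior_sd) slope priors.

    ``family`` is 'logistic' or 'gaussian'; ``group`` adds a per-level
    random intercept (variance components estimated by REML for the Gaussian
    family, by Laplace profile for the logistic family).
    """
    if family not in ("logistic", "gaussian"):
        raise ValueError("family must be 'logistic' or 'gaussian'")
    frame = data.reset_index(drop=True)
    y = frame[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(frame))] + [frame[p].to_numpy(dtype=float) for p in predictors])
    terms = ["intercept"] + list(predictors)
    p = X.shape[1]
    prior_prec = _prior_precision(p, prior_sd, intercept_prior_sd)
    rng = np.random.default_rng(seed)
    extra: dict = {}

    if family == "logistic" and group is None:
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("logistic outcome must be binary")
        beta, H = _newton_logistic(X, y, prior_prec)
        cov = np.linalg.inv(H)
        draws = rng.multivariate_normal(beta, cov, size=n_draws, method="cholesky")
        eta = X @ draws.T  # (n, S)
        ll = (y[:, None] * eta - np.logaddexp(0.0, eta)).T
        if np.max(np.abs(beta)) > 10:
            extra["separation_flag"] = True
    elif family == "logistic":
        beta, draws, ll, extra = _logistic_random_intercept(
            X, y, frame[group].to_numpy(), prior_prec, n_draws, rng
        )
    elif group is None:
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        sigma2 = float(resid @ resid / max(1, len(y) - p))
        A = X.T @ X / sigma2 + prior_prec
        cov = np.linalg.inv(A)
        beta = cov @ (X.T @ y / sigma2)
        draws = rng.multivariate_normal(beta, cov, size=n_draws, method="cholesky")
        mu = X @ draws.T
        ll = (-0.5 * np.log(2 * np.pi * sigma2) - (y[:, None] - mu) ** 2 / (2 * sigma2)).T
        extra["sigma"] = float(np.sqrt(sigma2))
    else:
        beta, draws, ll, extra = _gaussian_random_intercept(
            X, y, frame[group].to_numpy(), prior_prec, n_draws, rng
        )

    return GLMFit(
        family=family,
        coef=_coef_table(draws, terms),
        draws=draws,
        loglik_pointwise=ll,
        n_obs=len(y),
        outcome=y,
        terms=terms,
        extra=extra,
    )


def _anova_variance_components(X, y, codes):
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    groups = np.unique(codes)
    n_g = np.array([np.sum(codes == g) for g in groups])
    means = np.array([resid[codes == g].mean() for g in groups])
    N, G = len(y), len(groups)
    ss_within = float(sum(np.sum((resid[codes == g] - means[i]) ** 2) for i, g in enumerate(groups)))
    ms_within = ss_within / max(1, N - G)
    grand = resid.mean()
    ms_between = float(np.sum(n_g * (means - grand) ** 2)) / max(1, G - 1)
    n0 = (N - np.sum(n_g**2) / N) / max(1, G - 1)
    sigma_u2 = max(0.0, (ms_between - ms_within) / max(n0, 1e-12))
    return ms_within, sigma_u2


def _gaussian_random_intercept(X, y, groups, prior_prec, n_draws, rng):
    """Closed-form Gaussian posterior for fixed effects, conditional on
    REML variance components from statsmodels MixedLM."""
    import statsmodels.api as sm

    import warnings

    codes, _ = pd.factorize(groups)
    try:
        md = sm.MixedLM(y, X, groups=codes)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # boundary estimates (sigma_u ~ 0) are legitimate and handled
            warnings.simplefilter("ignore")
            mr = md.fit(reml=True, method="lbfgs", disp=False)
        sigma_e2 = float(mr.scale)
        cov_re = np.asarray(mr.cov_re)
        sigma_u2 = float(cov_re[0, 0]) if cov_re.size else 0.0
        if not (np.isfinite(sigma_e2) and np.isfinite(sigma_u2)):
            raise ValueError("non-finite variance components")
    except Exception:
        # small-group designs can defeat REML; fall back to the one-way
        # ANOVA moment estimator on OLS residuals
        sigma_e2, sigma_u2 = _anova_variance_components(X, y, codes)

    p = X.shape[1]
    A = np.array(prior_prec, dtype=float)
    b = np.zeros(p)
    for g in np.unique(codes):
        idx = codes == g
        Xg, yg = X[idx], y[idx]
        ng = int(idx.sum())
        shrink = sigma_u2 / (sigma_e2 + ng * sigma_u2)
        # V_g^{-1} = (I - shrink * 11') / sigma_e2
        XtV = (Xg.T - shrink * np.outer(Xg.sum(axis=0), np.ones(ng))) / sigma_e2
        A += XtV @ Xg
        b += XtV @ yg
    cov = np.linalg.inv(A)
    beta = cov @ b
    draws = rng.multivariate_normal(beta, cov, size=n_draws, method="cholesky")
    # pointwise marginal likelihood for LOO
    s2 = sigma_e2 + sigma_u2
    mu = X @ draws.T
    ll = (-0.5 * np.log(2 * np.pi * s2) - (y[:, None] - mu) ** 2 / (2 * s2)).T
    return beta, draws, ll, {"sigma_e": float(np.sqrt(sigma_e2)), "sigma_u": float(np.sqrt(sigma_u2))}


def _logistic_random_intercept(X, y, groups, prior_prec, n_draws, rng):
    """Laplace approximation over (fixed effects, random intercepts) with the
    random-intercept SD chosen by profiling the Laplace marginal."""
    from scipy.optimize import minimize_scalar

    codes, levels = pd.factorize(groups)
    n_g = len(levels)
    Z = np.zeros((len(y), n_g))
    Z[np.arange(len(y)), codes] = 1.0
    XZ = np.hstack([X, Z])
    p = X.shape[1]

    def joint_fit(log_su):
        su2 = np.exp(2 * log_su)
        prec = np.zeros((p + n_g, p + n_g))
        prec[:p, :p] = prior_prec
        prec[p:, p:] = np.eye(n_g) / su2
        beta_u, H = _newton_logistic(XZ, y, prec)
        eta = XZ @ beta_u
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        pen = -0.5 * float(beta_u @ prec @ beta_u) - 0.5 * n_g * np.log(su2)
        sign, logdet = np.linalg.slogdet(H)
        marg = ll + pen - 0.5 * logdet
        return marg, beta_u, H

    res = minimize_scalar(
        lambda ls: -joint_fit(ls)[0], bounds=(np.log(0.05), np.log(5.0)), method="bounded",
        options={"xatol": 1e-2},
    )
    _, beta_u, H = joint_fit(res.x)
    cov = np.linalg.inv(H)
    draws_full = rng.multivariate_normal(beta_u, cov, size=n_draws, method="cholesky")
    eta = XZ @ draws_full.T
    ll = (y[:, None] * eta - np.logaddexp(0.0, eta)).T
    return (
        beta_u[:p],
        draws_full[:, :p],
        ll,
        {"sigma_u": float(np.exp(res.x)), "random_intercept": True},
    )


# ---------------------------------------------------------------------------
# Analysis-table assembly and the named models


def build_analysis_table(
    trial_table: pd.DataFrame,
    cohort_table: pd.DataFrame | None = None,
    numeracy: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Assemble the tidy analysis table.

    ``trial_table`` needs participant_id, problem_type, chose_higher_ev,
    attention; ``cohort_table`` (from ``fit_cohort``) contributes theta_hat
    and alpha_hat per (participant, problem type); ``numeracy`` maps
    participant_id -> 0..7 score.
    """
    rows = trial_table.copy()
    if cohort_table is not None:
        rows = rows.merge(
            cohort_table[["participant_id", "problem_type", "theta_hat", "alpha_hat"]],
            on=["participant_id", "problem_type"],
            how="left",
        )
    if numeracy is not None:
        num = pd.Series(numeracy, name="numeracy")
        bad = set(num.dropna().astype(int)) - set(range(8))
        if bad:
            raise ValueError(f"numeracy scores outside 0..7: {sorted(bad)}")
        rows["numeracy"] = rows["participant_id"].map(num)
    return rows


def _subset(rows: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset not in SUBSETS:
        raise ValueError(f"subset must be one of {SUBSETS}")
    if subset == "all":
        return rows.copy()
    return rows[rows["problem_type"] == subset].copy()


def total_effect_model(
    rows: pd.DataFrame, subset: str = "all", random_intercept: bool = False, seed: int = 0
) -> GLMFit:
    """TEM: chose_higher_ev ~ z(numeracy), logistic."""
    frame = _subset(rows, subset)
    if frame.empty:
        raise ValueError(f"no rows in subset {subset!r}")
    frame["z_numeracy"] = z_standardize(frame["numeracy"])
    return fit_bayesian_glm(
        frame,
        outcome="chose_higher_ev",
        predictors=["z_numeracy"],
        family="logistic",
        group="participant_id" if random_intercept else None,
        seed=seed,
    )


def mediator_model(rows: pd.DataFrame, measure: str, seed: int = 0) -> GLMFit:
    """MM: process measure ~ z(numeracy) * problem type + (1 | participant).

    ``attention`` is modelled at trial level; ``alpha`` and ``theta`` at
    their native participant-by-problem-type grain (posterior means, their
    estimation uncertainty ignored). risky.better is the reference level.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    col = _MEASURE_COL[measure]
    if measure == "attention":
        frame = rows[["participant_id", "problem_type", col]].dropna().copy()
    else:
        frame = (
            rows[["participant_id", "problem_type", col, "numeracy"]]
            .dropna()
            .drop_duplicates(subset=["participant_id", "problem_type"])
            .copy()
        )
    if measure == "attention":
        frame = frame.merge(
            rows[["participant_id", "numeracy"]].drop_duplicates(), on="participant_id"
        )
    frame["z_numeracy"] = z_standardize(frame["numeracy"])
    frame["type_sb"] = (frame["problem_type"] == "safe.better").astype(float)
    frame["z_numeracy_x_type_sb"] = frame["z_numeracy"] * frame["type_sb"]
    return fit_bayesian_glm(
        frame,
        outcome=col,
        predictors=["z_numeracy", "type_sb", "z_numeracy_x_type_sb"],
        family="gaussian",
        group="participant_id",
        seed=seed,
    )


def direct_effect_model(
    rows: pd.DataFrame,
    measures: list[str],
    subset: str = "all",
    random_intercept: bool = False,
    seed: int = 0,
) -> GLMFit:
    """DEM: chose_higher_ev ~ z(numeracy) + z(measures...), logistic."""
    if not measures:
        raise ValueError("DEM needs at least one process-level measure (else use the TEM)")
    bad = set(measures) - set(MEASURES)
    if bad:
        raise ValueError(f"unknown measures: {sorted(bad)}")
    frame = _subset(rows, subset)
    cols = [_MEASURE_COL[m] for m in measures]
    frame = frame.dropna(subset=cols + ["numeracy"])
    if frame.empty:
        raise ValueError(f"no rows in subset {subset!r}")
    frame["z_numeracy"] = z_standardize(frame["numeracy"])
    predictors = ["z_numeracy"]
    for m, col in zip(measures, cols):
        if frame[col].std(ddof=1) == 0:
            # a constant mediator carries no information; dropping it keeps
            # the model well-posed and the numeracy coefficient unchanged
            warnings.warn(f"measure {m!r} is constant in subset {subset!r}; dropped", stacklevel=2)
            continue
        name = f"z_{m}"
        frame[name] = z_standardize(frame[col])
        predictors.append(name)
    return fit_bayesian_glm(
        frame,
        outcome="chose_higher_ev",
        predictors=predictors,
        family="logistic",
        group="participant_id" if random_intercept else None,
        seed=seed,
    )


def mediation_summary(tem: GLMFit, dems: dict[str, GLMFit] | list[GLMFit]) -> pd.DataFrame:
    """Compare the numeracy coefficient between the TEM and each DEM.

    Reports the coefficient, interval, credibility, absolute and relative
    reduction relative to the TEM, and loo-IC per model. All models must be
    fitted to the same outcome rows.
    """
    if isinstance(dems, list):
        dems = {f"DEM{i + 1}": d for i, d in enumerate(dems)}
    tem_beta = float(tem.coefficient("z_numeracy")["mean"])
    rows = [
        {
            "model": "TEM",
            "numeracy_beta": tem_beta,
            "q2.5": tem.coefficient("z_numeracy")["q2.5"],
            "q97.5": tem.coefficient("z_numeracy")["q97.5"],
            "credible": bool(tem.coefficient("z_numeracy")["credible"]),
            "reduction": 0.0,
            "reduction_pct": 0.0,
            "loo_ic": tem.loo_ic,
        }
    ]
    for name, dem in dems.items():
        if dem.n_obs != tem.n_obs or not np.array_equal(dem.outcome, tem.outcome):
            raise ValueError(f"{name}: DEM and TEM fitted to different outcome rows")
        beta = float(dem.coefficient("z_numeracy")["mean"])
        red = tem_beta - beta
        rows.append(
            {
                "model": name,
                "numeracy_beta": beta,
                "q2.5": dem.coefficient("z_numeracy")["q2.5"],
                "q97.5": dem.coefficient("z_numeracy")["q97.5"],
                "credible": bool(dem.coefficient("z_numeracy")["credible"]),
                "reduction": red,
                "reduction_pct": 100.0 * red / tem_beta if tem_beta != 0 else np.nan,
                "loo_ic": dem.loo_ic,
            }
        )
    return pd.DataFrame(rows)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, 1/(1 - R^2_j), for fixed-effect columns."""
    X = design.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    out = {}
    n = X.shape[0]
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        Xo = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[name] = 1.0 / max(1.0 - r2, 1e-12)
    return pd.Series(out, name="vif")


def loo_compare(fits: dict[str, GLMFit]) -> pd.DataFrame:
    """Rank models by loo-IC (ascending: better predictive performance first)."""
    names = list(fits)
    first = fits[names[0]]
    for name in names[1:]:
        if fits[name].n_obs != first.n_obs or not np.array_equal(fits[name].outcome, first.outcome):
            raise ValueError("loo comparison requires identical outcome rows across models")
    table = pd.DataFrame(
        {"model": names, "loo_ic": [fits[n].loo_ic for n in names]}
    ).sort_values("loo_ic", ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
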