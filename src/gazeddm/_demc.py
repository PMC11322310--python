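"""Differential-evolution Metropolis (DE-MC) sampler.

A population MCMC scheme (ter Braak 2006): each chain proposes a jump along
the difference of two other randomly chosen chains, scaled by
gamma = 2.38/sqrt(2*d), with occasional gamma = 1 mode-jumping proposals and
a small isotropic jitter. Well suited to the correlated, moderate-dimensional
posteriors of diffusion-model likelihoods, and cheap because the target can
be evaluated for the whole population at once.

The target callable must accept an (n_chains, dim) array and return a length
n_chains vector of log posterior densities (-inf outside support).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DEMCResult", "run_demc"]


@dataclass
class DEMCResult:
    draws: np.ndarray  # (n_chains, n_kept, dim)
    logpost: np.ndarray  # (n_chains, n_kept)
    accept_rate: float


def run_demc(
    log_post,
    init: np.ndarray,
    n_steps: int,
    n_burnin: int,
    rng: np.random.Generator,
    gamma_jump_prob: float = 0.1,
    jitter_sd: float = 1e-4,
) -> DEMCResult:
    """Run DE-MC from an (n_chains, dim) initial population."""
    x = np.array(init, dtype=float, copy=True)
    n_chains, dim = x.shape
    if n_chains < 4:
        raise ValueError("DE-MC needs at least 4 chains")
    lp = np.asarray(log_post(x), dtype=float)
    if not np.all(np.isfinite(lp)):
        bad = np.where(~np.isfinite(lp))[0]
        raise ValueError(f"non-finite log posterior at initialization for chains {bad}")

    gamma0 = 2.38 / np.sqrt(2.0 * dim)
    kept_x = np.empty((n_chains, n_steps - n_burnin, dim))
    kept_lp = np.empty((n_chains, n_steps - n_burnin))
    n_accept = 0
    for step in range(n_steps):
        # pick r1 != r2 != i for every chain
        r1 = rng.integers(0, n_chains - 1, size=n_chains)
        r1[r1 >= np.arange(n_chains)] += 1
        r2 = rng.integers(0, n_chains - 2, size=n_chains)
        # map r2 past both i and r1
        lo = np.minimum(np.arange(n_chains), r1)
        hi = np.maximum(np.arange(n_chains), r1)
        r2[r2 >= lo] += 1
        r2[r2 >= hi] += 1
        gamma = np.where(rng.random(n_chains) < gamma_jump_prob, 1.0, gamma0)
        prop = x + gamma[:, None] * (x[r1] - x[r2]) + rng.normal(0, jitter_sd, size=x.shape)
        lp_prop = np.asarray(log_post(prop), dtype=float)
        accept = np.log(rng.random(n_chains)) < (lp_prop - lp)
        x[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        if step >= n_burnin:
            kept_x[:, step - n_burnin] = x
            kept_lp[:, step - n_burnin] = lp
            n_accept += int(accept.sum())
    denom = max(1, (n_steps - n_burnin) * n_chains)
    return DEMCResult(draws=kept_x, logpost=kept_lp, accept_rate=n_accept / denom)
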