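"""Independent simulation oracles used by the tests.

These deliberately avoid the package's analytic machinery: first-passage
behavior is generated by a bridge-corrected Euler random walk, so agreement
with the package's series-based densities is a genuine cross-check.
"""

import numpy as np


def walk_first_passage(v, a, n_sims, rng, dt=None, t_max=80.0):
    """First-passage simulation for a unit-diffusion walk between +-a/2.

    Uses Brownian-bridge crossing probabilities within each Euler step, so
    the absorption law is accurate even at coarse step sizes. Returns
    (upper: bool array, decision_time: array).
    """
    if dt is None:
        # step size scaled to the mean decision time of the process
        mean_t = (a / (2 * abs(v))) * np.tanh(abs(v) * a / 2) if v != 0 else (a / 2) ** 2
        dt = float(np.clip(mean_t / 2000.0, 1e-4, 1e-3))
    upper = np.zeros(n_sims, bool)
    tdec = np.full(n_sims, np.nan)
    x = np.zeros(n_sims)
    active = np.arange(n_sims)
    sq = np.sqrt(dt)
    hi = a / 2.0
    for k in range(1, int(t_max / dt) + 1):
        z = rng.standard_normal(active.size)
        xn = x + v * dt + sq * z
        hit_up = xn >= hi
        hit_lo = xn <= -hi
        free = ~(hit_up | hit_lo)
        if free.any():
            xf, xnf = x[free], xn[free]
            p_up = np.exp(-2.0 * (hi - xf) * (hi - xnf) / dt)
            p_lo = np.exp(-2.0 * (hi + xf) * (hi + xnf) / dt)
            u = rng.random(xf.size)
            idx = np.where(free)[0]
            hit_up[idx[u < p_up]] = True
            hit_lo[idx[(u >= p_up) & (u < p_up + p_lo)]] = True
        done = hit_up | hit_lo
        if done.any():
            gone = active[done]
            upper[gone] = hit_up[done]
            tdec[gone] = k * dt
            keep = ~done
            active, x = active[keep], xn[keep]
        else:
            x = xn
        if active.size == 0:
            break
    return upper, tdec
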