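"""The Wiener first-passage likelihood behind the aDDM estimation.

Shows how a trial's drift rate is assembled from gaze proportions and the
options' expected values, and evaluates the first-passage-time density and
the closed-form choice probability.
"""

import numpy as np

from gazeddm.gaze import TrialGaze
from gazeddm.wfpt import (
    DriftCoefficients,
    WienerTrialParams,
    choice_probability,
    theta_from_coeffs,
    trial_drift,
    wfpt_logdensity,
)

coeffs = DriftCoefficients(beta0=0.0, beta1=0.06, beta2=0.03)
print(f"distortion factor theta = beta2/beta1 = {theta_from_coeffs(coeffs):.2f}")

gaze = TrialGaze(gaze_a=0.65, gaze_b=0.35)
delta = trial_drift(coeffs, gaze, (20.0, 36.0))
print(f"trial drift with 65% gaze on A (EVs 20 vs 36): delta = {delta:.3f} per second")

params = WienerTrialParams(drift=delta, alpha=3.2, t0=0.35)
print(f"P(absorb at upper boundary) = {choice_probability(params):.3f}")

for t in (0.8, 1.5, 3.0):
    up = np.exp(wfpt_logdensity(t, "upper", params))
    lo = np.exp(wfpt_logdensity(t, "lower", params))
    print(f"  density at rt={t:.1f}s: upper {up:.4f}, lower {lo:.4f}")
print(
    "\nPositive drift pushes probability mass toward the upper boundary "
    "(the higher-EV option) and toward earlier upper-boundary crossings."
)
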