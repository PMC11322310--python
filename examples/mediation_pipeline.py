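"""The full mediation pipeline on a small synthetic cohort.

Generates a cohort where numeracy shapes decision quality only through the
generative aDDM parameters (theta, alpha) and a small attention bias, fits
every participant, and asks whether the fitted process measures mediate the
numeracy -> decision quality link. Takes a few minutes.
"""

import warnings

warnings.filterwarnings("ignore")

from gazeddm.fitting import FitConfig, fit_cohort
from gazeddm.mediation import (
    build_analysis_table,
    direct_effect_model,
    mediation_summary,
    mediator_model,
    total_effect_model,
)
from gazeddm.synth import SyntheticConfig, generate_dataset

cfg = SyntheticConfig(n_participants=24, n_problems=80, seed=101)
ds = generate_dataset(cfg)
cohort, fits = fit_cohort(
    ds.trial_records(), FitConfig(n_chains=10, n_samples=2500, n_burnin=1250, seed=11)
)
rows = build_analysis_table(
    ds.analysis_trial_table(), cohort, ds.participants.set_index("participant_id")["numeracy"]
)

tem = total_effect_model(rows)
dem = direct_effect_model(rows, ["alpha", "theta"])
print(mediation_summary(tem, {"DEM(alpha,theta)": dem}).round(3).to_string(index=False))

mm = mediator_model(rows, "theta")
print("\nMediator model for theta (risky.better is the reference level):")
print(mm.coef.round(3))
print(
    "\nReading the table: the numeracy coefficient shrinking from the TEM to "
    "the DEM — and losing credibility — indicates that the fitted process "
    "measures statistically mediate the numeracy-decision quality link, "
    "which is exactly how the cohort was generated."
)
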