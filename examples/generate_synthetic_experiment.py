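"""Generate and write a complete synthetic eye-tracking experiment.

The generator emulates the study design the analysis assumes: 80
participants x 100 safe-vs-risky problems, numeracy-linked generative aDDM
parameters, alternating fixations, and millisecond choices/RTs. Here a
small cohort is produced and written as CSV files.
"""

from gazeddm.synth import SyntheticConfig, generate_dataset
from gazeddm.task import classify_problem

cfg = SyntheticConfig(n_participants=6, n_problems=40, seed=7)
ds = generate_dataset(cfg)

types = [classify_problem(p) for p in ds.problems]
print(f"{len(ds.problems)} problems ({types.count('risky.better')} risky.better)")
print(f"{len(ds.trials)} trials, {len(ds.fixations)} fixations")
print("\nparticipants (numeracy and true generative parameters):")
print(ds.participants[["participant_id", "numeracy", "theta_rb", "theta_sb", "alpha_rb", "alpha_sb"]].round(3).to_string(index=False))

tab = ds.analysis_trial_table()
print(f"\noverall decision quality: {tab['chose_higher_ev'].mean():.2f}")
print(f"mean attention to the higher-EV option: {tab['attention'].mean():.3f}")

ds.write("scratch/synthetic_experiment")
print("\nwrote problems.csv, participants.csv, trials.csv, fixations.csv to scratch/synthetic_experiment/")
print("(pass hide_truth=True to omit the generative parameters for blinded testing)")
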