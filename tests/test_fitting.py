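import numpy as np
import pandas as pd
import pytest

from gazeddm.fitting import (
    FitConfig,
    LowDataWarning,
    ParticipantFit,
    PARAM_NAMES,
    compute_rhat,
    fit_cohort,
    fit_participant,
    posterior_predict,
)
from gazeddm.gaze import Fixation
from gazeddm.simulate import ADDMGenerativeParams, FixationProcess, simulate_trial
from gazeddm.synth import SyntheticConfig, generate_dataset
from gazeddm.task import ChoiceProblem, Option
from gazeddm.wfpt import sim_to_likelihood_units

from conftest import make_trial

QUICK = FitConfig(n_chains=8, n_samples=1500, n_burnin=750, seed=5)


def constant_gaze_records(n_trials, theta=0.45, seed=3):
    """Trials with gaze locked on one option: the trial drift is exactly
    constant, so the Wiener likelihood is exact for the simulator."""
    rng = np.random.default_rng(seed)
    sim = ADDMGenerativeParams(d=1.3e-4, theta=theta, sigma=0.05, alpha=7.2, t0=350.0)
    problems = []
    grid = np.round(np.arange(0.05, 0.951, 0.05), 2)
    for i in range(n_trials):
        xs = int(rng.integers(5, 60))
        xr = int(rng.integers(xs + 5, 95))
        valid = grid[grid * xr > xs + 1e-9] if i % 2 == 0 else grid[grid * xr < xs - 1e-9]
        problems.append(ChoiceProblem(f"p{i}", Option.safe(xs), Option.risky(xr, float(rng.choice(valid)))))
    recs = []
    for i, prob in enumerate(problems):
        lock_a = rng.random() < 0.5
        fix = FixationProcess(first_fixation_p_a=1.0 if lock_a else 0.0, dwell_mean_a=1e7, dwell_mean_b=1e7)
        s = simulate_trial(sim, prob, fix, rng, max_steps=120_000)
        recs.append(make_trial(prob, s.fixations, s.choice, s.rt, tid=f"t{i}"))
    truth = sim_to_likelihood_units(sim.d, sim.sigma, sim.alpha, sim.t0)
    return recs, {"beta1": truth[0], "alpha": truth[1], "t0": truth[2], "theta": theta}


class TestFitParticipant:
    def test_recovery_exact_likelihood_regime(self):
        recs, truth = constant_gaze_records(260)
        fit = fit_participant(recs, FitConfig(n_chains=10, n_samples=3000, n_burnin=1500, seed=9))
        assert fit.posterior_mean("beta1") == pytest.approx(truth["beta1"], rel=0.3)
        assert fit.posterior_mean("alpha_rb") == pytest.approx(truth["alpha"], rel=0.15)
        assert fit.posterior_mean("alpha_sb") == pytest.approx(truth["alpha"], rel=0.15)
        assert fit.posterior_mean("t0") == pytest.approx(truth["t0"], abs=0.1)
        assert abs(fit.posterior_mean("theta_rb") - truth["theta"]) < 0.2
        assert abs(fit.posterior_mean("theta_sb") - truth["theta"]) < 0.2

    def test_theta_is_per_draw_ratio(self):
        recs, _ = constant_gaze_records(60)
        fit = fit_participant(recs, QUICK)
        np.testing.assert_allclose(
            fit.draws["theta_rb"], fit.draws["beta2_rb"] / fit.draws["beta1"]
        )

    def test_more_data_shrinks_posterior(self):
        recs, _ = constant_gaze_records(80)
        doubled = recs + [
            make_trial(r.problem, list(r.fixations), r.choice, r.rt_ms, tid=f"d{i}")
            for i, r in enumerate(recs)
        ]
        sd_small = fit_participant(recs, QUICK).summary.loc["beta1", "sd"]
        sd_large = fit_participant(doubled, QUICK).summary.loc["beta1", "sd"]
        assert sd_large < sd_small

    def test_seed_determinism(self):
        recs, _ = constant_gaze_records(60)
        a = fit_participant(recs, QUICK).summary
        b = fit_participant(recs, QUICK).summary
        pd.testing.assert_frame_equal(a, b)

    def test_default_settings_converge(self):
        # split-R-hat <= 1.01 for every parameter at the default sampler
        # settings on a default synthetic participant
        from gazeddm.synth import SyntheticConfig, generate_dataset

        ds = generate_dataset(SyntheticConfig(n_participants=1, n_problems=150, seed=33))
        fit = fit_participant(ds.trial_records(), FitConfig(seed=5))
        assert float(fit.summary["rhat"].max()) <= 1.01

    def test_low_data_warning(self):
        recs, _ = constant_gaze_records(12)
        with pytest.warns(LowDataWarning):
            fit_participant(recs, FitConfig(n_chains=8, n_samples=400, n_burnin=200, seed=1))


class TestRhat:
    def test_identical_chains_unity(self):
        chain = np.sin(np.linspace(0, 20, 500)) + np.linspace(0, 1, 500)
        rhat = compute_rhat(np.stack([chain, chain, chain, chain]))
        assert rhat["x"] == pytest.approx(1.0, abs=0.05)

    def test_stationary_chains_converge(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 4000))
        assert compute_rhat(chains)["x"] <= 1.01

    def test_displaced_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((4, 500)) + np.array([[0.0], [5.0], [-5.0], [10.0]])
        assert compute_rhat(chains)["x"] > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            compute_rhat(np.zeros((1, 100)))


def _manual_fit(beta0, beta1, beta2, alpha, t0):
    values = dict(
        beta0=beta0, beta1=beta1, beta2_rb=beta2, beta2_sb=beta2,
        alpha_rb=alpha, alpha_sb=alpha, t0=t0,
        theta_rb=beta2 / beta1, theta_sb=beta2 / beta1,
    )
    summary = pd.DataFrame(
        {"mean": values, "sd": 0.0, "q2.5": values, "q97.5": values, "rhat": 1.0}
    )
    summary.index.name = "parameter"
    return ParticipantFit(
        participant_id="m", summary=summary, draws={}, loglik=np.zeros((2, 2)),
        n_trials=0, accept_rate=1.0,
    )


class TestPosteriorPredict:
    problem = ChoiceProblem("p", Option.safe(20), Option.risky(60, 0.6))  # EVs 20 vs 36

    def _trials(self, choice, n=40):
        fixes = [Fixation("option_a", 300.0, 0.0), Fixation("option_b", 700.0, 300.0)]
        return [make_trial(self.problem, list(fixes), choice, 1400.0, tid=f"t{i}") for i in range(n)]

    def test_separable_limit_matches_everything(self):
        fit = _manual_fit(0.0, 5.0, 5.0, 4.0, 0.3)  # huge drift scale
        out = posterior_predict(fit, self._trials("option_b"))
        assert out["match_rate"] == 1.0

    def test_chance_level_under_zero_drift(self):
        fit = _manual_fit(0.0, 1e-12, 0.0, 2.0, 0.3)
        trials = self._trials("option_b", 200) + self._trials("option_a", 200)
        out = posterior_predict(fit, trials, mode="sample", rng=2)
        assert np.all(out["p_choose_higher_ev"] == pytest.approx(0.5))
        assert abs(out["match_rate"] - 0.5) < 3 * np.sqrt(0.25 / 400)

    def test_invalid_mode_rejected(self):
        fit = _manual_fit(0.0, 1.0, 0.5, 2.0, 0.3)
        with pytest.raises(ValueError):
            posterior_predict(fit, self._trials("option_b"), mode="bogus")


class TestFitCohort:
    def test_shape_contract_and_determinism(self):
        cfg = SyntheticConfig(n_participants=2, n_problems=30, seed=77)
        ds = generate_dataset(cfg)
        quick = FitConfig(n_chains=8, n_samples=600, n_burnin=300, seed=4)
        table, fits = fit_cohort(ds.trial_records(), quick)
        table2, _ = fit_cohort(ds.trial_records(), quick)
        assert len(table) == 4  # 2 participants x 2 problem types
        assert set(table["problem_type"]) == {"risky.better", "safe.better"}
        assert {"theta_hat", "alpha_hat", "rhat_max"} <= set(table.columns)
        pd.testing.assert_frame_equal(table, table2)
        assert set(fits) == {"s000", "s001"}
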