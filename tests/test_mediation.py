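import numpy as np
import pandas as pd
import pytest

from gazeddm.mediation import (
    build_analysis_table,
    direct_effect_model,
    fit_bayesian_glm,
    loo_compare,
    mediation_summary,
    mediator_model,
    total_effect_model,
    vif,
    z_standardize,
)


class TestZStandardize:
    def test_population_convention(self):
        out = z_standardize([1, 2, 3], ddof=0)
        np.testing.assert_allclose(out, [-1.22474487, 0.0, 1.22474487])

    def test_sample_convention_default(self):
        out = z_standardize([1, 2, 3])
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0)

    def test_idempotent_up_to_rescale(self):
        rng = np.random.default_rng(0)
        x = z_standardize(rng.standard_normal(50))
        np.testing.assert_allclose(z_standardize(x), x, atol=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            z_standardize([4, 4, 4])


def _logistic_data(beta, n, rng):
    x = rng.standard_normal(n)
    eta = beta[0] + beta[1] * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame({"y": y, "x": x})


class TestBayesGLM:
    def test_logistic_recovery(self):
        rng = np.random.default_rng(10)
        frame = _logistic_data((0.9, 0.2), 7000, rng)
        fit = fit_bayesian_glm(frame, "y", ["x"], "logistic", seed=1)
        coef = fit.coefficient("x")
        assert coef["q2.5"] < 0.2 < coef["q97.5"]
        assert fit.coefficient("intercept")["mean"] == pytest.approx(0.9, abs=0.15)

    def test_prior_shrinks_toward_zero(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        frame = _logistic_data((0.3, 0.8), 120, rng)
        bayes = fit_bayesian_glm(frame, "y", ["x"], "logistic", seed=2)
        X = sm.add_constant(frame["x"].to_numpy())
        flat = sm.GLM(frame["y"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert abs(bayes.coefficient("x")["mean"]) <= abs(flat.params[1])

    def test_gaussian_family_recovery(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(800)
        y = 0.5 + 0.4 * x + rng.normal(0, 0.7, 800)
        fit = fit_bayesian_glm(pd.DataFrame({"y": y, "x": x}), "y", ["x"], "gaussian", seed=3)
        coef = fit.coefficient("x")
        assert coef["mean"] == pytest.approx(0.4, abs=0.1)
        assert bool(coef["credible"])

    def test_invalid_family_and_nonbinary_outcome(self):
        frame = pd.DataFrame({"y": [0.0, 0.5, 1.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fit_bayesian_glm(frame, "y", ["x"], "poisson")
        with pytest.raises(ValueError):
            fit_bayesian_glm(frame, "y", ["x"], "logistic")


def _mediation_rows(n_participants=60, trials_per_cell=20, direct=0.0, link=0.08, seed=0):
    """Trial table where numeracy moves theta/alpha, which move choice."""
    rng = np.random.default_rng(seed)
    numeracy = rng.integers(0, 8, n_participants)
    z = (numeracy - numeracy.mean()) / numeracy.std()
    rows = []
    for i in range(n_participants):
        theta = {"risky.better": 0.45 + link * z[i] + rng.normal(0, 0.05),
                 "safe.better": 0.45 + 0.25 * link * z[i] + rng.normal(0, 0.05)}
        alpha = {"risky.better": 3.3 + 6 * link * z[i] + rng.normal(0, 0.3),
                 "safe.better": 3.5 + 6 * link * z[i] + rng.normal(0, 0.3)}
        for ptype in ("risky.better", "safe.better"):
            eta_base = 0.4 + 2.5 * (theta[ptype] - 0.45) + 0.6 * (alpha[ptype] - 3.4) + direct * z[i]
            for t in range(trials_per_cell):
                attention = np.clip(0.54 + rng.normal(0, 0.1), 0, 1)
                eta = eta_base + 0.8 * (attention - 0.54)
                rows.append(
                    {
                        "participant_id": f"s{i:03d}",
                        "problem_type": ptype,
                        "chose_higher_ev": float(rng.random() < 1 / (1 + np.exp(-eta))),
                        "attention": attention,
                        "theta_hat": theta[ptype],
                        "alpha_hat": alpha[ptype],
                        "numeracy": int(numeracy[i]),
                    }
                )
    return pd.DataFrame(rows)


class TestNamedModels:
    rows = _mediation_rows()

    def test_tem_detects_generative_link(self):
        tem = total_effect_model(self.rows)
        coef = tem.coefficient("z_numeracy")
        assert coef["mean"] > 0 and bool(coef["credible"])

    def test_tem_permuted_numeracy_usually_null(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(10):
            rows = self.rows.copy()
            perm = rows[["participant_id", "numeracy"]].drop_duplicates()
            rows["numeracy"] = rows["participant_id"].map(
                dict(zip(perm["participant_id"], rng.permutation(perm["numeracy"].to_numpy())))
            )
            tem = total_effect_model(rows, random_intercept=True, seed=rep)
            hits += bool(tem.coefficient("z_numeracy")["credible"])
        assert hits <= 3

    def test_mediator_model_signs(self):
        mm = mediator_model(self.rows, "theta")
        assert mm.coefficient("z_numeracy")["mean"] > 0
        assert bool(mm.coefficient("z_numeracy")["credible"])
        assert mm.coefficient("z_numeracy_x_type_sb")["mean"] < 0

    def test_mediator_model_unknown_measure(self):
        with pytest.raises(ValueError):
            mediator_model(self.rows, "pupil_size")

    def test_dem_reduces_numeracy_effect_under_full_mediation(self):
        tem = total_effect_model(self.rows)
        dem = direct_effect_model(self.rows, ["alpha", "theta"])
        summary = mediation_summary(tem, {"DEM(alpha,theta)": dem})
        red = summary.loc[summary["model"] == "DEM(alpha,theta)", "reduction"].item()
        assert red > 0
        assert summary.loc[summary["model"] == "DEM(alpha,theta)", "reduction_pct"].item() > 30

    def test_dem_with_irrelevant_mediator_changes_little(self):
        rows = self.rows.copy()
        rng = np.random.default_rng(9)
        rows["theta_hat"] = rng.standard_normal(len(rows))  # unrelated noise
        tem = total_effect_model(rows)
        dem = direct_effect_model(rows, ["theta"])
        summary = mediation_summary(tem, {"DEM": dem})
        assert abs(summary.loc[summary["model"] == "DEM", "reduction_pct"].item()) < 20

    def test_dem_requires_measures(self):
        with pytest.raises(ValueError):
            direct_effect_model(self.rows, [])

    def test_mediation_summary_identical_model_zero_reduction(self):
        tem = total_effect_model(self.rows, seed=0)
        summary = mediation_summary(tem, {"same": tem})
        assert summary.loc[summary["model"] == "same", "reduction"].item() == 0.0

    def test_constant_mediator_dropped_gives_zero_reduction(self):
        rows = self.rows.copy()
        rows["alpha_hat"] = 3.0
        tem = total_effect_model(rows, seed=0)
        with pytest.warns(UserWarning):
            dem = direct_effect_model(rows, ["alpha"], seed=0)
        summary = mediation_summary(tem, {"DEM": dem})
        assert summary.loc[summary["model"] == "DEM", "reduction"].item() == 0.0

    def test_subset_mismatch_rejected(self):
        tem = total_effect_model(self.rows, subset="risky.better")
        dem = direct_effect_model(self.rows, ["theta"], subset="safe.better")
        with pytest.raises(ValueError):
            mediation_summary(tem, {"DEM": dem})


class TestVIF:
    def test_orthogonal_predictors_unity(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        out = vif(pd.DataFrame({"x1": x1, "x2": x2}))
        np.testing.assert_allclose(out.to_numpy(), 1.0, atol=1e-10)

    def test_duplicated_predictor_rank_error(self):
        x = np.random.default_rng(0).standard_normal(50)
        with pytest.raises(ValueError):
            vif(pd.DataFrame({"x1": x, "x2": x}))

    def test_single_predictor_rejected(self):
        with pytest.raises(ValueError):
            vif(pd.DataFrame({"x1": np.arange(5.0)}))


class TestLooCompare:
    def test_true_model_ranks_first(self):
        rng = np.random.default_rng(20)
        frame = _logistic_data((0.2, 0.9), 1500, rng)
        full = fit_bayesian_glm(frame, "y", ["x"], "logistic", seed=1)
        frame0 = frame.assign(zero=0.0)
        null = fit_bayesian_glm(frame0.drop(columns="x").assign(x=0.0), "y", ["x"], "logistic", seed=1)
        table = loo_compare({"full": full, "intercept_only": null})
        assert table.loc[0, "model"] == "full"

    def test_noise_predictor_no_material_gain(self):
        rng = np.random.default_rng(21)
        frame = _logistic_data((0.2, 0.6), 1500, rng)
        frame["noise"] = rng.standard_normal(len(frame))
        base = fit_bayesian_glm(frame, "y", ["x"], "logistic", seed=1)
        bigger = fit_bayesian_glm(frame, "y", ["x", "noise"], "logistic", seed=1)
        assert bigger.loo_ic > base.loo_ic - 4.0

    def test_mismatched_rows_rejected(self):
        rng = np.random.default_rng(22)
        a = fit_bayesian_glm(_logistic_data((0.1, 0.3), 200, rng), "y", ["x"], "logistic")
        b = fit_bayesian_glm(_logistic_data((0.1, 0.3), 300, rng), "y", ["x"], "logistic")
        with pytest.raises(ValueError):
            loo_compare({"a": a, "b": b})


class TestBuildAnalysisTable:
    def test_merge_and_validation(self):
        trial_table = pd.DataFrame(
            {
                "participant_id": ["s0", "s0", "s1"],
                "problem_type": ["risky.better", "safe.better", "risky.better"],
                "chose_higher_ev": [1.0, 0.0, 1.0],
                "attention": [0.6, 0.5, 0.7],
            }
        )
        cohort = pd.DataFrame(
            {
                "participant_id": ["s0", "s0", "s1", "s1"],
                "problem_type": ["risky.better", "safe.better"] * 2,
                "theta_hat": [0.3, 0.4, 0.5, 0.6],
                "alpha_hat": [3.0, 3.2, 3.4, 3.6],
            }
        )
        rows = build_analysis_table(trial_table, cohort, {"s0": 3, "s1": 6})
        assert rows.loc[0, "theta_hat"] == 0.3
        assert rows.loc[2, "numeracy"] == 6
        with pytest.raises(ValueError):
            build_analysis_table(trial_table, cohort, {"s0": 9, "s1": 6})
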