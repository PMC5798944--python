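"""OLS, BIC, best-subsets selection, LOO validation, frozen models."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import chromotune as ct
from chromotune.regression import MissingFeatureError, _bic_value


def random_table(rng, n=14, covariates=ct.COVARIATE_COLUMNS):
    data = {"pigment_id": [f"p{i:02d}" for i in range(n)]}
    for c in covariates:
        data[c] = rng.normal(size=n)
    return pd.DataFrame(data)


def add_response(table, model=ct.FROZEN_PRIMARY, noise=0.0, rng=None):
    table = table.copy()
    y = np.full(len(table), model.intercept)
    for c, b in model.coefficients.items():
        y = y + b * table[c].to_numpy()
    if noise and rng is not None:
        y = y + rng.normal(scale=noise, size=len(table))
    table["lambda_max_nm"] = y
    return table


class TestOlsFit:
    def test_exact_recovery_of_generating_coefficients(self, rng):
        table = add_response(random_table(rng))
        m = ct.ols_fit(table, ["median_torsion15", "auc_rmsf_lysret"])
        assert m.intercept == pytest.approx(475.628, abs=1e-6)
        assert m.coefficients["median_torsion15"] == pytest.approx(-8.720, abs=1e-6)
        assert m.coefficients["auc_rmsf_lysret"] == pytest.approx(34.925, abs=1e-6)

    def test_matches_statsmodels(self, rng):
        table = add_response(random_table(rng), noise=5.0, rng=rng)
        subset = ["median_torsion1", "median_torsion15", "auc_rmsf_ring"]
        ours = ct.ols_fit(table, subset)
        X = sm.add_constant(table[subset].to_numpy())
        ref = sm.OLS(table["lambda_max_nm"].to_numpy(), X).fit()
        assert ours.intercept == pytest.approx(ref.params[0], rel=1e-8)
        for c, b in zip(subset, ref.params[1:]):
            assert ours.coefficients[c] == pytest.approx(b, rel=1e-8)
        assert ours.fit_stats["r_squared"] == pytest.approx(ref.rsquared, rel=1e-8)

    def test_constant_response(self, rng):
        table = random_table(rng)
        table["lambda_max_nm"] = 500.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = ct.ols_fit(table, ["median_torsion15"])
        assert m.coefficients["median_torsion15"] == pytest.approx(0.0, abs=1e-9)
        assert m.intercept == pytest.approx(500.0)
        assert m.fit_stats["r_squared"] == 0.0

    def test_residuals_orthogonal_to_design(self, rng):
        table = add_response(random_table(rng), noise=4.0, rng=rng)
        subset = ["median_torsion15", "auc_rmsf_lysret", "median_angle3"]
        m = ct.ols_fit(table, subset)
        pred = ct.predict_lambda_max(m, table)
        resid = table["lambda_max_nm"].to_numpy() - pred.to_numpy()
        assert abs(resid.sum()) < 1e-8
        for c in subset:
            assert abs(resid @ table[c].to_numpy()) < 1e-8

    def test_projection_idempotence(self, rng):
        table = add_response(random_table(rng), noise=4.0, rng=rng)
        subset = ["median_torsion15", "auc_rmsf_lysret"]
        m = ct.ols_fit(table, subset)
        fitted = table.copy()
        fitted["lambda_max_nm"] = ct.predict_lambda_max(m, table).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m2 = ct.ols_fit(fitted, subset)
        again = ct.predict_lambda_max(m2, table)
        assert np.allclose(again, fitted["lambda_max_nm"], atol=1e-8)

    def test_collinear_design_raises(self, rng):
        table = add_response(random_table(rng))
        table["auc_rmsf_ring"] = 2.0 * table["auc_rmsf_lysret"]
        with pytest.raises(ct.SingularDesignError):
            ct.ols_fit(table, ["auc_rmsf_ring", "auc_rmsf_lysret"])


class TestBic:
    def test_direct_evaluation(self):
        assert _bic_value(14, 14.0, 2) == pytest.approx(3 * np.log(14))

    def test_penalty_monotone_in_k(self):
        assert _bic_value(14, 20.0, 1) < _bic_value(14, 20.0, 2)

    def test_small_rss_gain_increases_bic(self):
        # reduction below the n^(-1/n) threshold cannot pay the ln(n) penalty
        n, rss = 14, 30.0
        shrunk = rss * (n ** (-1 / n)) * 1.01
        assert _bic_value(n, shrunk, 3) > _bic_value(n, rss, 2)

    def test_zero_rss_sentinel(self):
        with pytest.warns(UserWarning):
            assert _bic_value(10, 0.0, 2) == float("-inf")

    def test_model_accessor(self, rng):
        table = add_response(random_table(rng), noise=3.0, rng=rng)
        m = ct.ols_fit(table, ["median_torsion15"])
        assert ct.bic(m) == pytest.approx(m.fit_stats["bic"])


class TestBestSubsets:
    def test_pool_size_for_seven_covariates(self, rng):
        table = add_response(random_table(rng), noise=3.0, rng=rng)
        ranked = ct.best_subsets(table, nbest=7)
        # sum over k of min(7, C(7,k)) = 7+7+7+7+7+7+1
        assert len(ranked) == 43

    @pytest.mark.parametrize("p,nbest", [(3, 2), (4, 7), (5, 3)])
    def test_matches_brute_force_oracle(self, rng, p, nbest):
        covs = list(ct.COVARIATE_COLUMNS[:p])
        gen = ct.RegressionModel(500.0, {covs[0]: -5.0, covs[-1]: 10.0})
        table = add_response(random_table(rng, covariates=covs), model=gen,
                             noise=3.0, rng=rng)
        ranked = ct.best_subsets(table, nbest=nbest, covariates=covs)
        # oracle: fit every subset with statsmodels, retain per-k by RSS,
        # rank pooled by BIC with lexicographic tie-break
        pool = []
        for k in range(1, p + 1):
            fits = []
            for sub in itertools.combinations(covs, k):
                X = sm.add_constant(table[list(sub)].to_numpy())
                res = sm.OLS(table["lambda_max_nm"].to_numpy(), X).fit()
                rss = float(res.ssr)
                fits.append((rss, sub))
            fits.sort()
            pool.extend(fits[:nbest])
        oracle = sorted(
            pool,
            key=lambda t: (_bic_value(len(table), t[0], len(t[1])), t[1]),
        )
        assert [m.covariates for m in ranked] == [tuple(sub) for _, sub in oracle]
        for m, (rss, _) in zip(ranked, oracle):
            assert m.fit_stats["rss"] == pytest.approx(rss, rel=1e-9)

    def test_single_covariate(self, rng):
        covs = ["median_torsion15"]
        gen = ct.RegressionModel(480.0, {covs[0]: -8.0})
        table = add_response(random_table(rng, covariates=covs), model=gen,
                             noise=1.0, rng=rng)
        ranked = ct.best_subsets(table, covariates=covs)
        assert len(ranked) == 1
        assert ranked[0].covariates == ("median_torsion15",)

    def test_singular_subsets_skipped_not_fatal(self, rng):
        table = add_response(random_table(rng), noise=3.0, rng=rng)
        table["median_angle3"] = 1.0  # constant column, collinear with intercept
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked = ct.best_subsets(table, nbest=7)
        assert all("median_angle3" not in m.covariates for m in ranked)
        assert len(ranked) > 0


class TestLooValidate:
    def test_noise_free_predictions_exact(self, rng):
        table = add_response(random_table(rng))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ct.loo_validate(table, ["median_torsion15", "auc_rmsf_lysret"])
        obs = table.set_index("pigment_id")["lambda_max_nm"]
        assert res.pooled_r2 == pytest.approx(1.0, abs=1e-9)
        for pid, pred in res.predictions.items():
            assert pred == pytest.approx(obs[pid], abs=1e-6)

    def test_row_order_invariance(self, rng):
        table = add_response(random_table(rng), noise=3.0, rng=rng)
        shuffled = table.sample(frac=1.0, random_state=0)
        a = ct.loo_validate(table, ["median_torsion15"])
        b = ct.loo_validate(shuffled, ["median_torsion15"])
        pd.testing.assert_series_equal(a.predictions, b.predictions)

    def test_fold_excludes_held_out_row(self, rng):
        table = add_response(random_table(rng), noise=3.0, rng=rng)
        res = ct.loo_validate(table, ["median_torsion15"])
        # corrupting one pigment's response must not change its own fold model
        corrupted = table.copy()
        mask = corrupted["pigment_id"] == "p03"
        corrupted.loc[mask, "lambda_max_nm"] += 1000.0
        res2 = ct.loo_validate(corrupted, ["median_torsion15"])
        m1, m2 = res.fold_models["p03"], res2.fold_models["p03"]
        assert m1.intercept == pytest.approx(m2.intercept)
        assert m1.coefficients == pytest.approx(m2.coefficients)
        # but every other fold sees the corrupted value
        assert res.fold_models["p00"].intercept != pytest.approx(
            res2.fold_models["p00"].intercept)


class TestPredictAndFrozenModels:
    def test_frozen_primary_at_origin(self):
        assert ct.predict_lambda_max(
            ct.FROZEN_PRIMARY, {"median_torsion15": 0.0, "auc_rmsf_lysret": 0.0}
        ) == pytest.approx(475.628)

    def test_frozen_secondary_at_origin(self):
        assert ct.predict_lambda_max(
            ct.FROZEN_SECONDARY, {"median_torsion4": 0.0, "median_torsion14": 0.0}
        ) == pytest.approx(1190.6208)

    def test_unit_slopes(self):
        base = ct.predict_lambda_max(
            ct.FROZEN_PRIMARY, {"median_torsion15": 0.0, "auc_rmsf_lysret": 0.0})
        up_t = ct.predict_lambda_max(
            ct.FROZEN_PRIMARY, {"median_torsion15": 1.0, "auc_rmsf_lysret": 0.0})
        up_a = ct.predict_lambda_max(
            ct.FROZEN_PRIMARY, {"median_torsion15": 0.0, "auc_rmsf_lysret": 1.0})
        assert up_t - base == pytest.approx(-8.720)
        assert up_a - base == pytest.approx(34.925)

    def test_missing_covariate_raises(self):
        with pytest.raises(MissingFeatureError):
            ct.predict_lambda_max(ct.FROZEN_PRIMARY, {"median_torsion15": 0.0})

    def test_high_fluctuation_green_shifts(self, topo):
        """With Torsion 15 fixed, more mobile chromophores are predicted
        at longer wavelengths."""
        preds = []
        for jitter in (0.01, 0.04):
            spec = ct.PigmentSpec(
                "p", {"Torsion 15": [ct.VonMisesComponent(2.0, 400.0)]},
                jitter_scale=jitter, n_frames=300, seed=21)
            traj = ct.simulate_trajectory(spec)
            row = ct.build_feature_table([traj], topo).iloc[0]
            preds.append(ct.predict_lambda_max(ct.FROZEN_PRIMARY, row))
        assert preds[1] > preds[0]


class TestBuildFeatureTable:
    def test_empty_input_gives_empty_table(self):
        table = ct.build_feature_table([])
        assert len(table) == 0
        assert list(table.columns) == ["pigment_id", *ct.COVARIATE_COLUMNS]

    def test_failed_pigment_flagged_and_skipped(self, topo, rng):
        good = ct.simulate_trajectory(ct.PigmentSpec("good", n_frames=50, seed=0))
        # single-frame trajectory cannot yield an RMSF profile
        bad = ct.Trajectory("bad", topo.atom_names, good.coords[:1])
        with pytest.warns(UserWarning, match="bad"):
            table = ct.build_feature_table([good, bad], topo)
        assert list(table["pigment_id"]) == ["good"]

    def test_coefficient_convergence_as_noise_shrinks(self):
        errors = []
        for noise in (1.0, 0.1, 0.01):
            spec = ct.demo_cohort_spec(seed=17, n_frames=150, noise_sd=noise)
            trajs, lam = ct.simulate_cohort(spec)
            table = ct.build_feature_table(
                trajs, lambda_max=lam.set_index("pigment_id")["lambda_max_nm"])
            m = ct.ols_fit(table, ["median_torsion15", "auc_rmsf_lysret"])
            errors.append(
                abs(m.coefficients["median_torsion15"] + 8.720)
                + abs(m.coefficients["auc_rmsf_lysret"] - 34.925)
            )
        assert errors[0] > errors[1] > errors[2]
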