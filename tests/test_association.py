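import numpy as np
import pandas as pd
import pytest

from earlygrowth import association as assoc
from earlygrowth.errors import ConfigurationError, SingularModelError
from earlygrowth.imputation import impute_covariates


def _result(est, se, n=100, df=90, **kw):
    kw.setdefault("outcome", "y")
    kw.setdefault("term", "x")
    kw.setdefault("model", "m")
    return assoc.AssociationResult(
        estimate=est, se=se, ci_low=est - 2 * se, ci_high=est + 2 * se,
        p=0.5, n=n, df_resid=df, **kw,
    )


class TestPoolRubin:
    def test_identical_results_degenerate_pooling(self):
        pooled = assoc.pool_rubin([_result(0.10, 0.05)] * 5)
        assert pooled.estimate == pytest.approx(0.10)
        assert pooled.se == pytest.approx(0.05)  # zero between-imputation variance
        assert pooled.pooled

    def test_hand_computed_three_imputation_example(self):
        results = [_result(e, 0.05) for e in (0.1, 0.2, 0.3)]
        pooled = assoc.pool_rubin(results)
        W = 0.05**2
        B = np.var([0.1, 0.2, 0.3], ddof=1)
        T = W + (1 + 1 / 3) * B
        assert pooled.estimate == pytest.approx(0.2, abs=1e-12)
        assert pooled.se**2 == pytest.approx(T, abs=1e-12)
        assert pooled.se == pytest.approx(0.1258, abs=1e-4)

    def test_single_imputation_passthrough(self):
        one = _result(0.3, 0.1)
        pooled = assoc.pool_rubin([one])
        assert pooled.estimate == one.estimate and pooled.se == one.se and pooled.pooled

    def test_pooled_se_at_least_mean_within_se(self, rng):
        results = [_result(e, 0.07) for e in rng.normal(0, 0.1, 5)]
        assert assoc.pool_rubin(results).se >= 0.07

    def test_mismatched_specs_error(self):
        with pytest.raises(SingularModelError, match="mismatched"):
            assoc.pool_rubin([_result(0.1, 0.05), _result(0.1, 0.05, term="other")])

    def test_barnard_rubin_df_below_complete_data_df(self):
        results = [_result(e, 0.05, df=200) for e in (0.0, 0.2, 0.4)]
        pooled = assoc.pool_rubin(results)
        assert 1 < pooled.df_resid < 200


class TestFitLinearModel:
    def test_known_slope_recovered_exactly_noiseless(self, rng):
        x = rng.standard_normal(100)
        data = pd.DataFrame({"y": 1.0 + 0.5 * x, "x": x})
        res = assoc.fit_linear_model(data, "y", ["x"])[0]
        assert res.estimate == pytest.approx(0.5, abs=1e-12)

    def test_constant_exposure_rank_error_names_column(self, rng):
        data = pd.DataFrame({"y": rng.standard_normal(50), "x": 1.0})
        with pytest.raises(SingularModelError, match="x"):
            assoc.fit_linear_model(data, "y", ["x"])

    def test_too_few_rows_error(self, rng):
        data = pd.DataFrame({"y": rng.standard_normal(8), "x": rng.standard_normal(8)})
        with pytest.raises(SingularModelError, match="below"):
            assoc.fit_linear_model(data, "y", ["x"])

    def test_ci_contains_estimate(self, rng):
        data = pd.DataFrame({"y": rng.standard_normal(60), "x": rng.standard_normal(60)})
        res = assoc.fit_linear_model(data, "y", ["x"])[0]
        assert res.ci_low < res.estimate < res.ci_high


class TestPatternModel:
    def test_contrasts_against_reference(self, rng):
        n = 400
        levels = np.array(assoc.PATTERN_LEVELS)
        pat = levels[rng.integers(0, 9, n)]
        effect = np.where(pat == "deceleration/acceleration", 0.5, 0.0)
        data = pd.DataFrame({"pattern": pat, "y": effect + rng.standard_normal(n)})
        res = assoc.pattern_model(data, "y", model_tag="basic")
        assert len(res) == 8
        da = [r for r in res if r.term == "pat:deceleration/acceleration"][0]
        assert da.ci_low < 0.5 < da.ci_high

    def test_missing_pattern_children_excluded(self, rng):
        pat = pd.Series([None] * 50 + list(np.array(assoc.PATTERN_LEVELS)[np.tile(np.arange(9), 30)[:250]]))
        data = pd.DataFrame({"pattern": pat, "y": rng.standard_normal(300)})
        res = assoc.pattern_model(data, "y")
        assert res[0].n == 250


class TestInteraction:
    def test_all_missing_delta_error(self, rng):
        data = pd.DataFrame(
            {
                "y": rng.standard_normal(50),
                "fetal_delta": rng.standard_normal(50),
                "infant_delta": np.nan,
                "child_age_yr": 9.8,
                "sex_boy": rng.integers(0, 2, 50).astype(float),
            }
        )
        with pytest.raises(SingularModelError, match="missing"):
            assoc.interaction_test(data, "y")

    def test_detects_product_effect(self, rng):
        n = 2000
        f = rng.standard_normal(n)
        i = rng.standard_normal(n)
        data = pd.DataFrame(
            {
                "y": 0.3 * f * i + rng.standard_normal(n),
                "fetal_delta": f,
                "infant_delta": i,
                "child_age_yr": rng.normal(9.8, 0.3, n),
                "sex_boy": rng.integers(0, 2, n).astype(float),
            }
        )
        assert assoc.interaction_test(data, "y") < 1e-6


class TestStratified:
    def test_small_stratum_flagged_not_fitted(self, rng):
        n = 200
        data = pd.DataFrame(
            {
                "y": rng.standard_normal(n),
                "pwv_kg_per_yr": rng.normal(12, 2, n),
                "bmiap": rng.normal(17.6, 0.8, n),
                "ageap_mo": rng.normal(8.4, 0.9, n),
                "birth_size": ["SGA"] * 10 + ["AGA"] * 180 + ["LGA"] * 10,
            }
        )
        res = assoc.stratified_infant_models(data, "y")
        sga = [r for r in res if r.stratum == "SGA"]
        assert all(r.flag == "skipped-small-stratum" for r in sga)
        aga = [r for r in res if r.stratum == "AGA"]
        assert all(np.isfinite(r.estimate) for r in aga)


class TestImputation:
    def test_no_missing_gives_identical_copies(self, rng):
        data = pd.DataFrame({"a": rng.standard_normal(50), "b": rng.integers(0, 2, 50).astype(float)})
        out = impute_covariates(data, m=3, seed=1)
        for ds in out:
            pd.testing.assert_frame_equal(ds, data)

    def test_imputations_vary_and_observed_cells_fixed(self, rng):
        data = pd.DataFrame({"a": rng.standard_normal(200), "b": rng.standard_normal(200)})
        data.loc[rng.uniform(size=200) < 0.3, "b"] = np.nan
        out = impute_covariates(data, m=2, seed=3)
        obs = data["b"].notna()
        for ds in out:
            assert ds["b"].notna().all()
            assert (ds.loc[obs, "b"] == data.loc[obs, "b"]).all()
            pd.testing.assert_series_equal(ds["a"], data["a"])
        assert not (out[0].loc[~obs, "b"] == out[1].loc[~obs, "b"]).all()

    def test_seed_reproducibility(self, rng):
        data = pd.DataFrame({"a": rng.standard_normal(100), "b": rng.standard_normal(100)})
        data.loc[::4, "b"] = np.nan
        out1 = impute_covariates(data, m=2, seed=11)
        out2 = impute_covariates(data, m=2, seed=11)
        for d1, d2 in zip(out1, out2):
            pd.testing.assert_frame_equal(d1, d2)

    def test_mar_conditional_mean_recovered(self):
        # y = 2x + e, missing where x is large: marginal mean of observed y is
        # biased low, regression-based imputation corrects it
        biases = []
        for seed in range(12):
            rng = np.random.default_rng(500 + seed)
            n = 600
            x = rng.standard_normal(n)
            y = 2 * x + rng.normal(0, 0.5, n)
            data = pd.DataFrame({"x": x, "y": y})
            miss = (x > 0.3) & (rng.uniform(size=n) < 0.8)
            truth = data["y"].mean()
            data.loc[miss, "y"] = np.nan
            out = impute_covariates(data, m=5, seed=seed)
            est = np.mean([ds["y"].mean() for ds in out])
            biases.append(est - truth)
        mc_se = np.std(biases, ddof=1) / np.sqrt(len(biases))
        assert abs(np.mean(biases)) < max(3 * mc_se, 0.02)

    def test_fully_missing_covariate_error(self):
        data = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": np.nan})
        with pytest.raises(ConfigurationError, match="no observed"):
            impute_covariates(data, m=2, seed=0)

    def test_excess_missingness_error(self, rng):
        data = pd.DataFrame({"a": rng.standard_normal(100), "b": rng.standard_normal(100)})
        data.loc[:70, "b"] = np.nan
        with pytest.raises(ConfigurationError, match="missing"):
            impute_covariates(data, m=2, seed=0)

    def test_binary_covariate_imputed_as_binary(self, rng):
        data = pd.DataFrame(
            {"x": rng.standard_normal(300), "b": rng.integers(0, 2, 300).astype(float)}
        )
        data.loc[rng.uniform(size=300) < 0.2, "b"] = np.nan
        out = impute_covariates(data, m=2, seed=5)
        for ds in out:
            assert set(ds["b"].unique()) <= {0.0, 1.0}


class TestNoMultiplicityAdjustment:
    def test_results_expose_raw_p_only(self, rng):
        # every result carries an unadjusted two-sided p and nothing else
        data = pd.DataFrame({"y": rng.standard_normal(60), "x": rng.standard_normal(60)})
        res = assoc.fit_linear_model(data, "y", ["x"])[0]
        d = res.to_dict()
        assert "p" in d and not any(k.startswith(("p_adj", "q")) for k in d)
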