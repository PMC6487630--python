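import numpy as np
import pandas as pd
import pytest

from earlygrowth.errors import ConfigurationError
from earlygrowth.synthetic import (
    SimConfig,
    TRUE_PWV,
    simulate_cohort,
    true_reference_charts,
    write_cohort,
)


class TestConfigValidation:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_children=0)

    def test_rho_bound(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_children=10, tracking_rho=1.0)

    def test_invalid_probability(self):
        with pytest.raises(ConfigurationError, match="missing_rates"):
            SimConfig(n_children=10, missing_rates={"24mo": 1.3})


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        a = simulate_cohort(SimConfig(n_children=150, seed=9))
        b = simulate_cohort(SimConfig(n_children=150, seed=9))
        pd.testing.assert_frame_equal(a.wide, b.wide)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = simulate_cohort(SimConfig(n_children=150, seed=9))
        b = simulate_cohort(SimConfig(n_children=150, seed=10))
        assert not a.wide["birth_weight_g"].equals(b.wide["birth_weight_g"])


class TestLatentStructure:
    def test_tracking_correlation_birth_to_6mo(self):
        c = simulate_cohort(SimConfig(n_children=1000, seed=1, tracking_rho=0.7))
        r = np.corrcoef(c.truth["z_birth"], c.truth["z_6mo"])[0, 1]
        assert r == pytest.approx(0.7, abs=0.05)

    def test_sds_marginally_standard(self, cohort_mid):
        n = len(cohort_mid.truth)
        for col in ("z_20w", "z_birth", "z_24mo"):
            z = cohort_mid.truth[col]
            assert abs(z.mean()) < 4.0 / np.sqrt(n)  # within 4 Monte-Carlo SEs
            assert abs(z.std(ddof=1) - 1) < 0.07

    def test_crossing_fraction_matches_bivariate_normal_oracle(self):
        # with rho = 0 all time points are independent; the birth -> infancy
        # SDS change is N(0, 2) and the crossing probability follows by
        # brute-force Monte Carlo
        rng = np.random.default_rng(123)
        oracle = np.mean(rng.standard_normal(10**6) - rng.standard_normal(10**6) > 0.67)
        c = simulate_cohort(SimConfig(n_children=4000, seed=2, tracking_rho=0.0))
        frac = (c.truth["infant_delta"] > 0.67).mean()
        se = np.sqrt(oracle * (1 - oracle) / 4000)
        assert abs(frac - oracle) < 3.5 * se

    def test_catch_up_more_common_after_fetal_deceleration(self, cohort_mid):
        t = cohort_mid.truth
        p_accel_given_decel = (t.loc[t.fetal_category == "deceleration", "infant_category"] == "acceleration").mean()
        p_accel_given_accel = (t.loc[t.fetal_category == "acceleration", "infant_category"] == "acceleration").mean()
        assert p_accel_given_decel > p_accel_given_accel


@pytest.fixture(scope="module")
def big():
    return simulate_cohort(SimConfig(n_children=5000, seed=77))


class TestMissingness:
    def test_infant_availability_rates(self, big):
        w = big.wide
        p24 = w["weight_24mo_kg"].notna().mean()
        assert p24 == pytest.approx(0.663, abs=3.5 * np.sqrt(0.663 * 0.337 / 5000))
        no24 = w["weight_24mo_kg"].isna()
        p12_cond = w.loc[no24, "weight_12mo_kg"].notna().mean()
        assert p12_cond == pytest.approx(0.401, abs=0.035)
        neither = no24 & w["weight_12mo_kg"].isna()
        p6_cond = w.loc[neither, "weight_6mo_kg"].notna().mean()
        assert p6_cond == pytest.approx(0.152, abs=0.035)

    def test_fetal_completeness_rate(self, big):
        w = big.wide
        both = (w["ga_20w_wk"].notna() & w["ga_30w_wk"].notna()).mean()
        assert both == pytest.approx(0.714, abs=0.025)

    def test_missingness_depends_on_education(self, big):
        w = big.wide
        t = big.truth
        low = w["education"] == "lower"
        # lower-educated mothers have lower 24-month availability (MAR signal)
        assert w.loc[low, "weight_24mo_kg"].notna().mean() < w.loc[~low, "weight_24mo_kg"].notna().mean()

    def test_covariate_missingness_rates(self, big):
        w = big.wide
        assert w["folic_acid"].isna().mean() == pytest.approx(0.312, abs=0.03)
        assert w["education"].isna().mean() == pytest.approx(0.078, abs=0.02)


class TestGeneratedScales:
    def test_measurement_scales_match_cohort_tables(self, cohort_mid):
        w = cohort_mid.wide
        assert w["birth_weight_g"].mean() == pytest.approx(3444, abs=60)
        assert w["weight_6mo_kg"].median() == pytest.approx(7.8, abs=0.35)
        assert w["height_cm"].mean() == pytest.approx(141.7, abs=1.0)
        liver = w[[f"liver_fat_pct_s{i}" for i in range(1, 5)]].mean(axis=1)
        assert liver.median() == pytest.approx(2.0, abs=0.25)

    def test_true_pwv_and_adiposity_peak_scales(self, cohort_mid):
        t = cohort_mid.truth
        assert t["pwv_kg_per_yr"].mean() == pytest.approx(np.mean(list(TRUE_PWV.values())), abs=0.15)
        assert t["ageap_mo"].median() == pytest.approx(8.5, abs=0.6)
        assert t["bmiap"].median() == pytest.approx(17.6, abs=0.4)

    def test_hadlock_round_trip_on_generated_biometry(self, cohort_mid):
        # biometry is constructed so the Hadlock formula reproduces the
        # latent EFW; SDS against the generating charts recover the AR(1)
        from earlygrowth.pipeline import derive_efw, derive_sds

        charts = true_reference_charts()
        sds = derive_sds(cohort_mid.wide, derive_efw(cohort_mid.wide), charts)
        for col, z in (("sds_20w", "z_20w"), ("sds_birth", "z_birth"), ("sds_24mo", "z_24mo")):
            diff = (sds[col] - cohort_mid.truth[z]).dropna()
            assert diff.abs().max() < 5e-3


class TestNullGenerator:
    def test_zero_effects_give_null_associations(self):
        # with all outcome effects off, the pattern coefficient is centred
        # on zero across seeds
        from earlygrowth.pipeline import build_body_composition, derive_efw, derive_sds
        from earlygrowth import indices, patterns
        from earlygrowth.association import pattern_model

        charts = true_reference_charts()
        ests = []
        for seed in range(15):
            c = simulate_cohort(
                SimConfig(n_children=500, seed=900 + seed, effect_map={}, covariate_effects={})
            )
            sds = derive_sds(c.wide, derive_efw(c.wide), charts)
            pt = patterns.pattern_table(sds)
            panel = indices.build_outcomes(build_body_composition(c.wide))
            data = pd.concat([panel[["liver_fat_fraction_sds"]], pt[["pattern"]]], axis=1)
            res = pattern_model(data, "liver_fat_fraction_sds", model_tag="basic")
            ests.append([r.estimate for r in res if r.term == "pat:deceleration/acceleration"][0])
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 3 * mc_se


class TestWriteCohort:
    def test_round_trip_identity(self, tmp_path):
        from earlygrowth.io import read_cohort, read_observations

        c = simulate_cohort(SimConfig(n_children=120, seed=4))
        p = tmp_path / "cohort.csv"
        po = tmp_path / "obs.csv"
        write_cohort(c, p, observations_path=po)
        back = read_cohort(p)
        assert len(back) == 120
        for col in c.wide.columns:
            orig = c.wide[col]
            got = back[col]
            if orig.dtype == object:
                assert (got.fillna("") == orig.fillna("")).all()
            else:
                assert np.allclose(got.to_numpy(dtype=float), orig.to_numpy(dtype=float), equal_nan=True)
        obs = read_observations(po)
        assert len(obs) == len(c.observations)

    def test_missing_serialized_as_empty_fields(self, tmp_path):
        c = simulate_cohort(SimConfig(n_children=200, seed=4))
        p = tmp_path / "cohort.csv"
        write_cohort(c, p)
        text = p.read_text().splitlines()
        assert any(",," in line for line in text[1:])
        from earlygrowth.io import read_cohort

        back = read_cohort(p)
        assert back["weight_24mo_kg"].isna().sum() == c.wide["weight_24mo_kg"].isna().sum()
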