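import numpy as np
import pandas as pd
import pytest

from earlygrowth import trajectories as tj
from earlygrowth.errors import DomainError, SingularModelError


def _reed1_obs(coef_by_sex, ages, n_per_sex=50, noise=0.0, rng=None):
    rows = []
    cid = 0
    for sex, (A, B, C, D) in coef_by_sex.items():
        for _ in range(n_per_sex):
            cid += 1
            w = tj.reed1_weight(ages, A, B, C, D)
            if noise and rng is not None:
                w = w + rng.normal(0, noise, len(ages))
            rows.append(pd.DataFrame({"child_id": cid, "sex": sex, "age_yr": ages, "weight_kg": w}))
    return pd.concat(rows, ignore_index=True)


class TestReed1Fit:
    def test_noiseless_exact_recovery_per_child(self):
        ages = np.array([0.1, 0.3, 0.6, 1.0, 1.5, 2.0])
        obs = _reed1_obs({"boy": (3.0, 10.0, 4.0, 1.0)}, ages, n_per_sex=5)
        fit = tj.fit_reed1(obs, method="per_child")
        assert fit.fixed["boy"] == pytest.approx([3.0, 10.0, 4.0, 1.0], abs=1e-6)
        assert fit.children[["A", "B", "C", "D"]].to_numpy() == pytest.approx(
            np.tile([3.0, 10.0, 4.0, 1.0], (5, 1)), abs=1e-6
        )

    def test_mixed_model_recovers_fixed_effects_under_noise(self, rng):
        ages = np.array([0.08, 0.15, 0.3, 0.5, 0.75, 1.0, 1.3, 1.6, 1.9, 2.05])
        obs = _reed1_obs({"boy": (3.0, 10.0, 4.0, 1.0)}, ages, n_per_sex=200, noise=0.1, rng=rng)
        fit = tj.fit_reed1(obs, method="mixed")
        assert fit.fixed["boy"] == pytest.approx([3.0, 10.0, 4.0, 1.0], abs=0.15)

    def test_observation_at_zero_age_rejected(self):
        obs = pd.DataFrame({"child_id": [1], "sex": ["boy"], "age_yr": [0.0], "weight_kg": [3.4]})
        with pytest.raises(DomainError):
            tj.fit_reed1(obs)

    def test_all_ages_equal_singular(self):
        obs = pd.DataFrame(
            {"child_id": np.arange(20), "sex": "boy", "age_yr": 0.5, "weight_kg": np.linspace(6, 9, 20)}
        )
        with pytest.raises(SingularModelError):
            tj.fit_reed1(obs, method="per_child", min_obs_per_child=1)


class TestReed1Peak:
    def test_closed_form_example(self):
        t_peak, pwv, flag = tj.reed1_peak(10.0, 4.0, 1.0)
        assert (t_peak, pwv, flag) == (pytest.approx(0.5), pytest.approx(14.0), "interior")

    def test_closed_form_matches_grid_search(self, rng):
        B = rng.uniform(5, 15, 300)
        C = rng.uniform(0.5, 5, 300)
        D = rng.uniform(0.02, 1, 300)
        t_peak, pwv, flag = tj.reed1_peak(B, C, D)
        step = 1e-4
        tt = np.arange(0.001, 2.0001, step)
        interior = flag == "interior"
        v = tj.reed1_velocity(tt[None, :], B[interior, None], C[interior, None], D[interior, None])
        idx = np.argmax(v, axis=1)
        # the grid locates the argmax to one step; the peak value agrees to 1e-3
        assert np.all(np.abs(tt[idx] - t_peak[interior]) <= 1.5 * step)
        assert np.all(np.abs(v[np.arange(interior.sum()), idx] - pwv[interior]) / pwv[interior] < 1e-3)

    def test_nonpositive_c_flagged_boundary(self):
        _, _, flag = tj.reed1_peak(10.0, -1.0, 0.5)
        assert flag == "boundary"

    def test_degenerate_limit_pwv_near_b(self):
        _, pwv, flag = tj.reed1_peak(12.0, 1e-4, 1e-4)
        assert pwv == pytest.approx(12.0, abs=0.02)

    def test_per_child_peaks_from_fit(self):
        ages = np.array([0.1, 0.3, 0.6, 1.0, 1.5, 2.0])
        obs = _reed1_obs({"girl": (3.0, 10.0, 4.0, 1.0)}, ages, n_per_sex=4)
        fit = tj.fit_reed1(obs, method="per_child")
        peaks = tj.peak_weight_velocity(fit)
        assert peaks["pwv_kg_per_yr"].to_numpy() == pytest.approx(np.full(4, 14.0), abs=1e-5)
        assert peaks["t_peak_yr"].to_numpy() == pytest.approx(np.full(4, 0.5), abs=1e-6)


class TestLogBmiCubic:
    BETA = (2.833, 0.0576, -0.0048, 0.0001)

    def _cubic_obs(self, rng=None, noise=0.0, n=40, sex_effect=0.0):
        ages = np.array([0.6, 2.0, 4.0, 6.0, 9.0, 12.0, 15.0, 17.5])
        rows = []
        for cid in range(n):
            sex = "boy" if cid % 2 else "girl"
            b0, b1, b2, b3 = self.BETA
            y = b0 + b1 * ages + b2 * ages**2 + b3 * ages**3 + (sex_effect if sex == "boy" else 0)
            if noise and rng is not None:
                y = y + rng.normal(0, noise, len(ages))
            rows.append(pd.DataFrame({"child_id": cid, "sex": sex, "age_mo": ages, "bmi": np.exp(y)}))
        return pd.concat(rows, ignore_index=True)

    def test_recovery_with_small_noise(self, rng):
        obs = self._cubic_obs(rng, noise=0.01, n=150, sex_effect=0.02)
        fit = tj.fit_logbmi_cubic(obs)
        assert fit.beta == pytest.approx(self.BETA, abs=5e-3)
        assert fit.sex_effect == pytest.approx(0.02, abs=5e-3)

    def test_too_few_distinct_ages_singular(self):
        obs = pd.DataFrame(
            {"child_id": np.arange(30), "sex": "boy", "age_mo": np.tile([3.0, 6.0, 9.0], 10), "bmi": 17.0}
        )
        with pytest.raises(SingularModelError):
            tj.fit_logbmi_cubic(obs)


class TestCubicPeak:
    def test_worked_example(self):
        # roots of 3*b3 t^2 + 2*b2 t + b1 are 8 and 24; only 8 is admissible
        ageap = tj.cubic_peak(0.0576, -0.0048, 0.0001)
        assert ageap == pytest.approx(8.0, abs=1e-9)

    def test_bmiap_from_fit(self):
        b0, b1, b2, b3 = 2.833, 0.0576, -0.0048, 0.0001
        children = pd.DataFrame({"child_id": [1], "sex": ["girl"], "b0_offset": [0.0], "b1_offset": [0.0]})
        fit = tj.LogBmiCubicFit(beta=np.array([b0, b1, b2, b3]), sex_effect=0.0, children=children)
        peak = tj.adiposity_peak(fit)
        assert peak["ageap_mo"][0] == pytest.approx(8.0, abs=1e-9)
        assert peak["bmiap"][0] == pytest.approx(np.exp(3.0378), abs=1e-3)  # ~20.86

    def test_quadratic_limit_is_vertex(self):
        assert tj.cubic_peak(0.06, -0.005, 0.0) == pytest.approx(6.0)

    def test_flat_and_monotone_curves_flagged_missing(self):
        assert np.isnan(tj.cubic_peak(0.0, 0.0, 0.0))
        assert np.isnan(tj.cubic_peak(0.1, 0.0, 0.0))  # strictly increasing

    def test_roots_outside_window_missing(self):
        # vertex at 24 months only
        assert np.isnan(tj.cubic_peak(0.48, -0.01, 0.0))

    def test_matches_numeric_argmax(self, rng):
        b2 = -rng.uniform(0.002, 0.02, 400)
        b1 = rng.uniform(0.02, 0.3, 400)
        b3 = rng.normal(0, 2e-4, 400)
        peak = tj.cubic_peak(b1, b2, b3)
        ok = ~np.isnan(peak)
        tt = np.arange(0.5, 18.0005, 1e-3)
        curve = b1[ok, None] * tt + b2[ok, None] * tt**2 + b3[ok, None] * tt**3
        num = tt[np.argmax(curve, axis=1)]
        interior = (num > 0.51) & (num < 17.99)
        assert np.all(np.abs(num[interior] - peak[ok][interior]) <= 2e-3)


class TestCohortTrajectories:
    def test_mean_pwv_matches_generating_value(self):
        # per-child OLS over several seeds; generating mean is the sex-mix
        # weighted Reed1 fixed-effect PWV
        from earlygrowth.synthetic import REED1_TRUE, SimConfig, TRUE_PWV, simulate_cohort

        means = []
        for seed in range(5):
            c = simulate_cohort(SimConfig(n_children=350, seed=300 + seed))
            obs = c.observations.copy()
            obs["age_yr"] = obs["age_mo"] / 12.0
            fit = tj.fit_reed1(obs, method="mixed")
            peaks = tj.peak_weight_velocity(fit)
            means.append(peaks["pwv_kg_per_yr"].mean())
        overall = np.mean(means)
        assert abs(overall - np.mean(list(TRUE_PWV.values()))) < 0.3
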