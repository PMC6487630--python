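"""Synthetic longitudinal cohort generator.

Emulates a prenatal-to-school-age cohort: weight SDS follow a stationary
first-order autoregressive (AR(1)) process across the six ordered time
points (20 and 30 gestational weeks, birth, 6, 12 and 24 months), which
reproduces tracking together with regression to the mean — so infant
catch-up growth is more common after fetal growth deceleration.  Raw
measurements are reconstructed from the latent SDS by inverting smooth
population reference curves; fetal biometry is scaled so the Hadlock
formula returns exactly the latent estimated fetal weight.  School-age
adiposity outcomes are generated on the natural-log scale as
linear-in-covariates Gaussian variables with configurable growth-pattern
effects.  Missingness of infant weights follows the configured fallback
availability rates and is missing-at-random given maternal education;
covariate missingness likewise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .anthro import HADLOCK_COEF
from .errors import ConfigurationError
from .patterns import classify_change
from .trajectories import reed1_weight

# --------------------------------------------------------------------------
# Generating population curves (the synthetic cohort's "true" references)
# --------------------------------------------------------------------------
#: True Reed1 fixed coefficients (A, B, C, D), weight in kg, age in years.
REED1_TRUE = {"boy": (8.118, 1.712, 1.758, 0.0704), "girl": (7.754, 1.673, 1.700, 0.0731)}

#: True peak weight velocity implied by REED1_TRUE: B + C^2/(4D).
TRUE_PWV = {s: c[1] + c[2] ** 2 / (4 * c[3]) for s, c in REED1_TRUE.items()}

# The population infant length curve is defined implicitly: log BMI is an
# exact cubic in age (peak at 8.4 months, BMIAP 17.6 girls / 17.7 boys),
# and L(t) = 100 * sqrt(W(t) / BMI(t)) with W the Reed1 weight curve — so
# infant BMI follows the functional form the adiposity-peak model assumes.
TRUE_LOGBMI_CUBIC = np.array([2.62771665, 6.80415894e-2, -5.98854793e-3, 1.53845502e-4])
_LOGBMI_SEX_SHIFT = {"girl": 0.0, "boy": float(np.log(17.7 / 17.6))}
_LEN_24MO = {"girl": 87.2, "boy": 88.6}  # beyond the cubic window (18-24.8 mo)
_WSD_ANCHOR_MO = np.array([0.5, 3.0, 6.2, 11.1, 24.8])
_WSD_ANCHORS = np.array([0.55, 0.75, 0.88, 1.03, 1.49])
_LSD_ANCHORS = np.array([2.0, 2.2, 2.3, 2.4, 2.8])

_EFW_GA_ANCHOR = np.array([13.0, 20.6, 30.4, 40.0])
_EFW_LOGMU = np.log(np.array([73.0, 378.0, 1622.0, 3444.0]))
_EFW_LOGSD = np.array([0.24, 0.2322, 0.1526, 0.1599])

# biometry base curves (cm) used to back out HC/AC/FL from a target EFW
_BIO_GA_ANCHOR = np.array([13.0, 20.6, 30.4, 40.0])
_HC_BASE = np.array([9.0, 17.8, 28.4, 34.0])
_AC_BASE = np.array([7.0, 15.6, 26.2, 35.0])
_FL_BASE = np.array([1.1, 3.3, 5.7, 7.5])

_BW_GA_ANCHOR = np.array([33.0, 36.0, 38.0, 40.0, 41.0, 42.5])
_BW_MU = np.array([2000.0, 2700.0, 3150.0, 3480.0, 3650.0, 3800.0])
_BW_SD = np.array([350.0, 400.0, 430.0, 440.0, 440.0, 440.0])
_BW_SEX_SHIFT = 60.0  # boys +, girls -

# childhood outcome scale parameters: median index value and log-scale SD
_OUTCOMES = ("fat_mass", "fat_free_mass", "visceral_fat", "pericardial_fat", "liver_fat")
_INDEX_MEDIAN = {"fat_mass": 2.1, "fat_free_mass": 12.5, "visceral_fat": 125.8, "pericardial_fat": 3.73}
_HEIGHT_POWER = {"fat_mass": 4, "fat_free_mass": 2, "visceral_fat": 3, "pericardial_fat": 3}
_LOG_SD = {"fat_mass": 0.36, "fat_free_mass": 0.10, "visceral_fat": 0.46, "pericardial_fat": 0.41, "liver_fat": 0.35}
_LIVER_MEDIAN = 2.0
_LIVER_SAMPLE_SD = 0.15

#: Default combined-pattern outcome effects, in outcome-SDS units
#: (fetal/infant category; the normal/normal reference is 0).
DEFAULT_EFFECT_MAP: dict[str, dict[str, float]] = {
    "visceral_fat": {
        "deceleration/deceleration": -0.01, "deceleration/normal": -0.22, "deceleration/acceleration": 0.18,
        "normal/deceleration": -0.08, "normal/acceleration": 0.07,
        "acceleration/deceleration": -0.08, "acceleration/normal": 0.08, "acceleration/acceleration": 0.05,
    },
    "liver_fat": {
        "deceleration/deceleration": -0.06, "deceleration/normal": -0.06, "deceleration/acceleration": 0.34,
        "normal/deceleration": -0.11, "normal/acceleration": 0.09,
        "acceleration/deceleration": -0.06, "acceleration/normal": 0.03, "acceleration/acceleration": -0.08,
    },
    "pericardial_fat": {
        "deceleration/deceleration": -0.07, "deceleration/normal": -0.08, "deceleration/acceleration": -0.09,
        "normal/deceleration": 0.05, "normal/acceleration": -0.07,
        "acceleration/deceleration": 0.15, "acceleration/normal": 0.08, "acceleration/acceleration": 0.08,
    },
}

DEFAULT_COVARIATE_EFFECTS: dict[str, Any] = {
    "smoking": {"fat_mass": 0.10, "visceral_fat": 0.10, "liver_fat": 0.10},
    "education_low": {"fat_mass": 0.08, "visceral_fat": 0.08, "liver_fat": 0.08},
    "prepregnancy_bmi_z": {"fat_mass": 0.15, "visceral_fat": 0.12, "liver_fat": 0.12, "pericardial_fat": 0.08},
    "sex_girl": {"fat_mass": 0.35, "fat_free_mass": -0.35},
}

DEFAULT_MISSING_RATES = {
    "fetal_complete": 0.714,
    "24mo": 0.663,
    "12mo_given_no_24": 0.401,
    "6mo_given_neither": 0.152,
    "12mo_base": 0.85,
    "6mo_base": 0.85,
    "extra_visit": 0.92,
}

DEFAULT_OUTCOME_AVAILABILITY = {"visceral": 0.852, "liver": 0.954, "pericardial": 0.886, "dxa": 0.97}

DEFAULT_COVARIATE_MISSING = {
    "maternal_age": 0.0,
    "prepregnancy_bmi": 0.05,
    "education": 0.078,
    "parity": 0.036,
    "folic_acid": 0.312,
    "smoking": 0.204,
    "ethnicity": 0.02,
    "breastfeeding": 0.155,
}

DEFAULT_MARGINALS = {
    "boy": 0.491,
    "education_low": 0.474,
    "smoking": 0.228,
    "folic_acid": 0.798,
    "parity_multi": 0.422,
    "non_european": 0.321,
    "breastfed_ever": 0.928,
}


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort."""

    n_children: int
    seed: int = 0
    tracking_rho: float = 0.7
    conditional_effect_map: dict[str, dict[str, float]] = field(default_factory=dict)
    effect_map: dict[str, dict[str, float]] = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECT_MAP.items()})
    covariate_effects: dict[str, Any] = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()})
    trajectory_effect_map: dict[str, dict[str, float]] = field(default_factory=dict)
    interaction_effects: dict[str, float] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    outcome_availability: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_AVAILABILITY))
    covariate_missing_rate: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COVARIATE_MISSING))
    covariate_marginals: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    mar_strength: float = 0.10
    outcome_cross_loading: float = 0.6

    def __post_init__(self):
        if self.n_children < 1:
            raise ConfigurationError("n_children must be >= 1")
        if not abs(self.tracking_rho) < 1:
            raise ConfigurationError("|tracking_rho| must be < 1")
        for name, probs in (
            ("missing_rates", self.missing_rates),
            ("outcome_availability", self.outcome_availability),
            ("covariate_missing_rate", self.covariate_missing_rate),
            ("covariate_marginals", self.covariate_marginals),
        ):
            for k, v in probs.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(f"{name}[{k!r}] = {v} outside [0, 1]")
        if not 0.0 <= self.outcome_cross_loading < 1.0:
            raise ConfigurationError("outcome_cross_loading must be in [0, 1)")


@dataclass
class SyntheticCohort:
    """Generated cohort: wide per-child table, long infant observations,
    and the latent truth used to create them."""

    wide: pd.DataFrame
    observations: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig


def _interp(x, xp, fp):
    return np.interp(np.asarray(x, dtype=float), xp, fp)


def _pop_length(sex: str, age_mo):
    """Population median infant length (cm) implied by the Reed1 weight
    curve and the cubic log-BMI trajectory; linear from 18 to 24.8 months."""
    t = np.asarray(age_mo, dtype=float)
    w = reed1_weight(t / 12.0, *REED1_TRUE[sex])
    c0, c1, c2, c3 = TRUE_LOGBMI_CUBIC
    logbmi = c0 + _LOGBMI_SEX_SHIFT[sex] + c1 * t + c2 * t**2 + c3 * t**3
    length = 100.0 * np.sqrt(w / np.exp(logbmi))
    hi = t > 18.0
    if np.any(hi):
        w18 = reed1_weight(1.5, *REED1_TRUE[sex])
        lb18 = c0 + _LOGBMI_SEX_SHIFT[sex] + c1 * 18.0 + c2 * 18.0**2 + c3 * 18.0**3
        l18 = 100.0 * np.sqrt(w18 / np.exp(lb18))
        frac = (t[hi] - 18.0) / (24.8 - 18.0)
        length[hi] = l18 + frac * (_LEN_24MO[sex] - l18)
    return length


def _biometry_from_efw(ga, efw):
    """HC/AC/FL (cm) whose Hadlock EFW equals the target exactly.

    The base biometry curves at the gestational age are scaled by a common
    multiplier m solving the (quadratic in m) Hadlock equation; the root
    nearer 1 is taken.
    """
    hc0 = _interp(ga, _BIO_GA_ANCHOR, _HC_BASE)
    ac0 = _interp(ga, _BIO_GA_ANCHOR, _AC_BASE)
    fl0 = _interp(ga, _BIO_GA_ANCHOR, _FL_BASE)
    a = HADLOCK_COEF["ac_fl"] * ac0 * fl0
    b = HADLOCK_COEF["hc"] * hc0 + HADLOCK_COEF["ac"] * ac0 + HADLOCK_COEF["fl"] * fl0
    c = HADLOCK_COEF["intercept"] - np.log10(efw)
    disc = np.sqrt(b**2 - 4 * a * c)
    m1 = (-b + disc) / (2 * a)
    m2 = (-b - disc) / (2 * a)
    m = np.where(np.abs(m1 - 1) <= np.abs(m2 - 1), m1, m2)
    return m * hc0, m * ac0, m * fl0


def _mar_probability(base, edu_low, strength):
    """Education-tilted probability whose marginal stays at ``base``."""
    q = float(np.mean(edu_low))
    s = min(strength, base, 1.0 - base)
    p_low = np.clip(base - s * (1.0 - q), 0.0, 1.0)
    p_high = np.clip(base + s * q, 0.0, 1.0)
    return np.where(edu_low, p_low, p_high)


def _effect_for(mapping, outcome):
    """Resolve a covariate/trajectory effect entry to a scalar per outcome."""
    if isinstance(mapping, dict):
        return float(mapping.get(outcome, 0.0))
    return float(mapping)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a cohort under the configured study conditions."""
    n = config.n_children
    rng = np.random.default_rng(config.seed)
    rho = config.tracking_rho
    marg = config.covariate_marginals

    sex = np.where(rng.uniform(size=n) < marg["boy"], "boy", "girl")
    is_boy = sex == "boy"

    # -- covariates (latent, fully observed; missingness applied at the end)
    maternal_age = rng.normal(31.1, 4.9, n)
    prepreg_bmi_z = rng.standard_normal(n)
    prepregnancy_bmi = 22.5 * np.exp(0.163 * prepreg_bmi_z)
    edu_low = rng.uniform(size=n) < marg["education_low"]
    smoking = rng.uniform(size=n) < marg["smoking"]
    folic = rng.uniform(size=n) < marg["folic_acid"]
    parity_multi = rng.uniform(size=n) < marg["parity_multi"]
    non_eu = rng.uniform(size=n) < marg["non_european"]
    breastfed = rng.uniform(size=n) < marg["breastfed_ever"]

    # -- visit ages
    ga2 = np.clip(rng.normal(20.6, 1.1, n), 18.5, 23.0)
    ga3 = np.clip(rng.normal(30.4, 1.0, n), 28.5, 32.5)
    ga_birth = np.clip(rng.normal(40.0, 1.5, n), 33.0, 42.5)
    age6 = np.clip(rng.normal(6.2, 0.5, n), 5.0, 8.0)
    age12 = np.clip(rng.normal(11.1, 0.6, n), 9.8, 13.0)
    age24 = np.clip(rng.normal(24.8, 1.2, n), 23.0, 28.5)
    child_age = rng.normal(9.8, 0.3, n)

    # -- AR(1) latent weight SDS across the six ordered time points.
    #    eps holds the standardized innovations: for an AR(1), the
    #    conditional growth variable at time k equals eps[:, k].
    Z = np.empty((n, 6))
    eps = np.empty((n, 6))
    eps[:, 0] = rng.standard_normal(n)
    Z[:, 0] = eps[:, 0]
    innov_sd = np.sqrt(1.0 - rho**2)
    for k in range(1, 6):
        eps[:, k] = rng.standard_normal(n)
        Z[:, k] = rho * Z[:, k - 1] + innov_sd * eps[:, k]

    # -- fetal measurements: EFW from the latent SDS, biometry backed out
    efw2 = np.exp(_interp(ga2, _EFW_GA_ANCHOR, _EFW_LOGMU) + Z[:, 0] * _interp(ga2, _EFW_GA_ANCHOR, _EFW_LOGSD))
    efw3 = np.exp(_interp(ga3, _EFW_GA_ANCHOR, _EFW_LOGMU) + Z[:, 1] * _interp(ga3, _EFW_GA_ANCHOR, _EFW_LOGSD))
    hc2, ac2, fl2 = _biometry_from_efw(ga2, efw2)
    hc3, ac3, fl3 = _biometry_from_efw(ga3, efw3)

    # -- birth weight
    bw_mu = _interp(ga_birth, _BW_GA_ANCHOR, _BW_MU) + np.where(is_boy, _BW_SEX_SHIFT, -_BW_SEX_SHIFT)
    bw = bw_mu + Z[:, 2] * _interp(ga_birth, _BW_GA_ANCHOR, _BW_SD)
    bw = np.maximum(bw, 400.0)

    # -- infant weights and lengths at the three visits
    def infant_weight(age_mo, z):
        w = np.empty(n)
        for s, coef in REED1_TRUE.items():
            m = sex == s
            w[m] = reed1_weight(age_mo[m] / 12.0, *coef)
        return w + z * _interp(age_mo, _WSD_ANCHOR_MO, _WSD_ANCHORS)

    zlen = {}
    def infant_length(age_mo, z_weight, key):
        zl = 0.7 * z_weight + np.sqrt(1 - 0.49) * rng.standard_normal(n)
        zlen[key] = zl
        length = np.empty(n)
        for s in REED1_TRUE:
            m = sex == s
            length[m] = _pop_length(s, age_mo[m])
        return length + zl * _interp(age_mo, _WSD_ANCHOR_MO, _LSD_ANCHORS)

    w6 = infant_weight(age6, Z[:, 3])
    w12 = infant_weight(age12, Z[:, 4])
    w24 = infant_weight(age24, Z[:, 5])
    l6 = infant_length(age6, Z[:, 3], "6")
    l12 = infant_length(age12, Z[:, 4], "12")
    l24 = infant_length(age24, Z[:, 5], "24")

    # -- per-child infant curve offsets: a z-score line in age, matched to
    #    the latent SDS at the 6- and 24-month visits; the child's weight
    #    deviation at any age is z(t) times the age-specific SD, so the
    #    relative deviation stays realistic at early ages too
    t6, t24 = age6 / 12.0, age24 / 12.0
    bz_off = (Z[:, 5] - Z[:, 3]) / (t24 - t6)
    az_off = Z[:, 3] - bz_off * t6
    lbz_off = (zlen["24"] - zlen["6"]) / (t24 - t6)
    laz_off = zlen["6"] - lbz_off * t6

    def curve_weight(age_mo):
        w = np.empty(n)
        for s, coef in REED1_TRUE.items():
            m = sex == s
            w[m] = reed1_weight(age_mo[m] / 12.0, *coef)
        zline = az_off + bz_off * age_mo / 12.0
        return w + zline * _interp(age_mo, _WSD_ANCHOR_MO, _WSD_ANCHORS)

    def curve_length(age_mo):
        length = np.empty(n)
        for s in REED1_TRUE:
            m = sex == s
            length[m] = _pop_length(s, age_mo[m])
        zline = laz_off + lbz_off * age_mo / 12.0
        return length + zline * _interp(age_mo, _WSD_ANCHOR_MO, _LSD_ANCHORS)

    # -- true per-child peak weight velocity from the smooth weight curve
    tgrid_mo = np.linspace(0.5, 18.0, 351)  # 0.05-month velocity grid
    wgrid = np.empty((n, tgrid_mo.size))
    for j, g in enumerate(tgrid_mo):
        wgrid[:, j] = curve_weight(np.full(n, g))
    vel = np.gradient(wgrid, tgrid_mo / 12.0, axis=1)
    vidx = np.argmax(vel, axis=1)
    true_pwv = vel[np.arange(n), vidx]

    # -- true per-child adiposity peak from the smooth infant BMI curve
    grid = np.linspace(0.6, 17.9, 180)
    bmi_grid = np.empty((n, grid.size))
    for j, g in enumerate(grid):
        gm = np.full(n, g)
        bmi_grid[:, j] = curve_weight(gm) / (curve_length(gm) / 100.0) ** 2
    peak_idx = np.argmax(bmi_grid, axis=1)
    true_ageap = grid[peak_idx]
    true_bmiap = bmi_grid[np.arange(n), peak_idx]

    # -- true growth pattern (effects attach to the pattern at the time
    #    point the fallback rule will select, so recovery is a measurement
    #    question, not a misclassification one)
    mr = config.missing_rates
    p24 = _mar_probability(mr["24mo"], edu_low, config.mar_strength)
    has24 = rng.uniform(size=n) < p24
    has12 = np.where(has24, rng.uniform(size=n) < mr["12mo_base"], rng.uniform(size=n) < mr["12mo_given_no_24"])
    has6 = np.where(
        has24 | has12, rng.uniform(size=n) < mr["6mo_base"], rng.uniform(size=n) < mr["6mo_given_neither"]
    )
    src_idx = np.where(has24, 5, np.where(has12, 4, np.where(has6, 3, 5)))
    z_infant_sel = Z[np.arange(n), src_idx]
    infant_source_true = np.where(has24, "24mo", np.where(has12, "11mo", np.where(has6, "6mo", "none")))

    fetal_delta_true = Z[:, 2] - Z[:, 0]
    infant_delta_true = z_infant_sel - Z[:, 2]
    fet_cat = np.asarray(classify_change(fetal_delta_true), dtype=object)
    inf_cat = np.asarray(classify_change(infant_delta_true), dtype=object)
    true_pattern = np.array([f"{f}/{i}" for f, i in zip(fet_cat, inf_cat)], dtype=object)

    # -- childhood outcomes on the log scale
    height10 = 141.7 + 6.7 * (0.3 * Z[:, 5] + np.sqrt(1 - 0.09) * rng.standard_normal(n))
    h_m = height10 / 100.0
    g_factor = rng.standard_normal(n)
    lam = config.outcome_cross_loading
    resid_sd = np.sqrt(1.0 - lam**2)

    pwv_c = true_pwv - true_pwv.mean()
    bmiap_c = true_bmiap - true_bmiap.mean()
    ageap_c = true_ageap - true_ageap.mean()
    raw: dict[str, np.ndarray] = {}
    for oc in _OUTCOMES:
        z = lam * g_factor + resid_sd * rng.standard_normal(n)
        eff = config.effect_map.get(oc, {})
        z = z + np.array([eff.get(p, 0.0) for p in true_pattern])
        for cov, val in config.covariate_effects.items():
            e = _effect_for(val, oc)
            if e == 0.0:
                continue
            x = {
                "smoking": smoking.astype(float),
                "education_low": edu_low.astype(float),
                "prepregnancy_bmi_z": prepreg_bmi_z,
                "sex_girl": (~is_boy).astype(float),
                "maternal_age_z": (maternal_age - 31.1) / 4.9,
                "non_european": non_eu.astype(float),
                "breastfed_ever": breastfed.astype(float),
            }.get(cov)
            if x is None:
                raise ConfigurationError(f"unknown covariate effect {cov!r}")
            z = z + e * x
        cond_eff = config.conditional_effect_map.get(oc, {})
        for tp, e in cond_eff.items():
            k = {"20w": 0, "30w": 1, "birth": 2, "6mo": 3, "12mo": 4, "24mo": 5}[tp]
            z = z + e * eps[:, k]
        traj = config.trajectory_effect_map.get(oc, {})
        z = z + traj.get("pwv", 0.0) * pwv_c + traj.get("bmiap", 0.0) * bmiap_c + traj.get("ageap", 0.0) * ageap_c
        z = z + config.interaction_effects.get(oc, 0.0) * fetal_delta_true * infant_delta_true
        if oc == "liver_fat":
            raw[oc] = _LIVER_MEDIAN * np.exp(_LOG_SD[oc] * z)
        else:
            raw[oc] = _INDEX_MEDIAN[oc] * h_m ** _HEIGHT_POWER[oc] * np.exp(_LOG_SD[oc] * z)

    fat_mass = raw["fat_mass"]
    fat_free_mass = raw["fat_free_mass"]
    weight10 = (fat_mass + fat_free_mass) * 1.04 + rng.normal(0, 0.3, n)
    visceral_vol = raw["visceral_fat"] / 0.9
    pericardial_vol = raw["pericardial_fat"] / 0.9
    liver_samples = raw["liver_fat"][:, None] + rng.normal(0, _LIVER_SAMPLE_SD, (n, 4))
    liver_samples = np.maximum(liver_samples, 0.05)

    child_id = np.arange(1, n + 1)
    wide = pd.DataFrame(
        {
            "child_id": child_id,
            "sex": sex,
            "maternal_age": maternal_age,
            "prepregnancy_bmi": prepregnancy_bmi,
            "parity": parity_multi.astype(float),
            "education": np.where(edu_low, "lower", "higher"),
            "smoking": np.where(smoking, "yes", "no"),
            "folic_acid": np.where(folic, "yes", "no"),
            "ethnicity": np.where(non_eu, "non_european", "european"),
            "breastfeeding": np.where(breastfed, "ever", "never"),
            "ga_20w_wk": ga2,
            "hc_20w_cm": hc2,
            "ac_20w_cm": ac2,
            "fl_20w_cm": fl2,
            "ga_30w_wk": ga3,
            "hc_30w_cm": hc3,
            "ac_30w_cm": ac3,
            "fl_30w_cm": fl3,
            "birth_ga_wk": ga_birth,
            "birth_weight_g": bw,
            "age_6mo_mo": age6,
            "weight_6mo_kg": w6,
            "length_6mo_cm": l6,
            "age_12mo_mo": age12,
            "weight_12mo_kg": w12,
            "length_12mo_cm": l12,
            "age_24mo_mo": age24,
            "weight_24mo_kg": w24,
            "length_24mo_cm": l24,
            "child_age_yr": child_age,
            "height_cm": height10,
            "weight_kg": weight10,
            "fat_mass_kg": fat_mass,
            "fat_free_mass_kg": fat_free_mass,
            "visceral_fat_vol_ml": visceral_vol,
            "pericardial_fat_vol_ml": pericardial_vol,
            "liver_fat_pct_s1": liver_samples[:, 0],
            "liver_fat_pct_s2": liver_samples[:, 1],
            "liver_fat_pct_s3": liver_samples[:, 2],
            "liver_fat_pct_s4": liver_samples[:, 3],
        }
    )

    # -- long infant observation table (trajectory modelling input)
    obs_rows = []
    extra_schedule = [(0.5, 0.1), (3.0, 0.3), (9.0, 0.4), (14.0, 0.5)]
    p_extra = mr["extra_visit"]
    for sched, jit in extra_schedule:
        age_mo = np.clip(rng.normal(sched, jit, n), 0.35, None)
        wobs = curve_weight(age_mo) + rng.normal(0, 0.10, n)
        lobs = curve_length(age_mo) + rng.normal(0, 0.35, n)
        present = rng.uniform(size=n) < p_extra
        obs_rows.append(
            pd.DataFrame(
                {"child_id": child_id, "sex": sex, "age_mo": age_mo, "weight_kg": wobs, "length_cm": lobs}
            )[present]
        )
    for age_mo, wv, lv, present in ((age6, w6, l6, has6), (age12, w12, l12, has12), (age24, w24, l24, has24)):
        obs_rows.append(
            pd.DataFrame(
                {"child_id": child_id, "sex": sex, "age_mo": age_mo, "weight_kg": wv, "length_cm": lv}
            )[present]
        )
    observations = pd.concat(obs_rows, ignore_index=True).sort_values(["child_id", "age_mo"])
    observations = observations.reset_index(drop=True)

    # -- apply missingness to the wide table
    fetal_complete = rng.uniform(size=n) < mr["fetal_complete"]
    drop_20w = ~fetal_complete & (rng.uniform(size=n) < 0.5)
    drop_30w = ~fetal_complete & ~drop_20w
    for cols, gone in (
        (["ga_20w_wk", "hc_20w_cm", "ac_20w_cm", "fl_20w_cm"], drop_20w),
        (["ga_30w_wk", "hc_30w_cm", "ac_30w_cm", "fl_30w_cm"], drop_30w),
        (["age_6mo_mo", "weight_6mo_kg", "length_6mo_cm"], ~has6),
        (["age_12mo_mo", "weight_12mo_kg", "length_12mo_cm"], ~has12),
        (["age_24mo_mo", "weight_24mo_kg", "length_24mo_cm"], ~has24),
    ):
        wide.loc[gone, cols] = np.nan

    av = config.outcome_availability
    wide.loc[rng.uniform(size=n) >= av["visceral"], "visceral_fat_vol_ml"] = np.nan
    wide.loc[rng.uniform(size=n) >= av["pericardial"], "pericardial_fat_vol_ml"] = np.nan
    liver_gone = rng.uniform(size=n) >= av["liver"]
    wide.loc[liver_gone, ["liver_fat_pct_s1", "liver_fat_pct_s2", "liver_fat_pct_s3", "liver_fat_pct_s4"]] = np.nan
    dxa_gone = rng.uniform(size=n) >= av["dxa"]
    wide.loc[dxa_gone, ["fat_mass_kg", "fat_free_mass_kg"]] = np.nan

    cmr = config.covariate_missing_rate
    cov_cols = {
        "maternal_age": "maternal_age",
        "prepregnancy_bmi": "prepregnancy_bmi",
        "education": "education",
        "parity": "parity",
        "folic_acid": "folic_acid",
        "smoking": "smoking",
        "ethnicity": "ethnicity",
        "breastfeeding": "breastfeeding",
    }
    tilted = {"folic_acid", "smoking", "breastfeeding"}
    for key, col in cov_cols.items():
        base = cmr.get(key, 0.0)
        if base <= 0:
            continue
        p = _mar_probability(base, edu_low, config.mar_strength) if key in tilted else np.full(n, base)
        gone = rng.uniform(size=n) < p
        if wide[col].dtype == object:
            wide.loc[gone, col] = None
        else:
            wide.loc[gone, col] = np.nan

    truth = pd.DataFrame(
        {
            "child_id": child_id,
            "sex": sex,
            "z_20w": Z[:, 0],
            "z_30w": Z[:, 1],
            "z_birth": Z[:, 2],
            "z_6mo": Z[:, 3],
            "z_12mo": Z[:, 4],
            "z_24mo": Z[:, 5],
            "fetal_delta": fetal_delta_true,
            "infant_delta": infant_delta_true,
            "fetal_category": fet_cat,
            "infant_category": inf_cat,
            "pattern": true_pattern,
            "infant_source": infant_source_true,
            "pwv_kg_per_yr": true_pwv,
            "ageap_mo": true_ageap,
            "bmiap": true_bmiap,
            "g_factor": g_factor,
        }
    )
    for j, tp in enumerate(("20w", "30w", "birth", "6mo", "12mo", "24mo")):
        truth[f"eps_{tp}"] = eps[:, j]
    return SyntheticCohort(wide=wide, observations=observations, truth=truth, config=config)


def true_reference_charts():
    """The generating population curves as :class:`ReferenceChart` objects.

    These play the role of the external (national/WHO-style) reference
    charts a real study would use: exact smooth references free of the
    sampling noise an internally fitted chart carries.  Converting the
    generated measurements to SDS against them recovers the latent AR(1)
    scores exactly.
    """
    from .reference import ReferenceChart

    ga = np.unique(np.concatenate([np.arange(13.0, 42.51, 0.25), _EFW_GA_ANCHOR]))
    efw_grid = pd.DataFrame(
        {"age": ga, "mean": _interp(ga, _EFW_GA_ANCHOR, _EFW_LOGMU), "sd": _interp(ga, _EFW_GA_ANCHOR, _EFW_LOGSD)}
    )
    gab = np.unique(np.concatenate([np.arange(33.0, 42.51, 0.25), _BW_GA_ANCHOR]))
    bw_grids = {
        s: pd.DataFrame(
            {
                "age": gab,
                "mean": _interp(gab, _BW_GA_ANCHOR, _BW_MU) + (_BW_SEX_SHIFT if s == "boy" else -_BW_SEX_SHIFT),
                "sd": _interp(gab, _BW_GA_ANCHOR, _BW_SD),
            }
        )
        for s in ("boy", "girl")
    }
    mo = np.unique(np.concatenate([np.arange(0.5, 28.51, 0.05), _WSD_ANCHOR_MO]))
    infant_grids = {
        s: pd.DataFrame(
            {
                "age": mo,
                "mean": reed1_weight(mo / 12.0, *REED1_TRUE[s]),
                "sd": _interp(mo, _WSD_ANCHOR_MO, _WSD_ANCHORS),
            }
        )
        for s in ("boy", "girl")
    }
    return {
        "efw": ReferenceChart(
            measure="efw", axis="gestational-weeks", sex_specific=False, transform="log",
            grids={"all": efw_grid}, support={"all": (ga[0], ga[-1])},
        ),
        "birth_weight": ReferenceChart(
            measure="birth_weight", axis="gestational-weeks", sex_specific=True,
            grids=bw_grids, support={s: (gab[0], gab[-1]) for s in bw_grids},
        ),
        "infant_weight": ReferenceChart(
            measure="infant_weight", axis="postnatal-months", sex_specific=True,
            grids=infant_grids, support={s: (mo[0], mo[-1]) for s in infant_grids},
        ),
    }


def write_cohort(cohort: SyntheticCohort, path, observations_path=None) -> None:
    """Write the wide per-child table (and optionally the long observation
    table) as CSV; missing values serialize as empty fields."""
    cohort.wide.to_csv(path, index=False)
    if observations_path is not None:
        cohort.observations.to_csv(observations_path, index=False)
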