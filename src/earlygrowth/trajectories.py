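"""Infant growth trajectory models: Reed1 weight curve and log(BMI) cubic.

Reed1 models weight as W(t) = A + B*t + C*ln(t) + D/t (t in years), linear
in its parameters, fitted per sex with per-child offsets on the intercept
and linear term.  Weight velocity v(t) = B + C/t - D/t**2 has an interior
maximum at t* = 2D/C with peak weight velocity PWV = B + C**2/(4D) whenever
C > 0 and D > 0.

The adiposity peak comes from a cubic mixed model on log(BMI) over ages
2 weeks to 1.5 years (t in months), adjusted for sex, with per-child
offsets on the intercept and linear term; the age at adiposity peak
(AGEAP) is the interior maximum of the per-child cubic and BMIAP the BMI
attained there.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, SingularModelError

log = logging.getLogger(__name__)

#: Minimum modelling age for Reed1 (ln t and 1/t blow up at t=0): 2 weeks.
REED1_MIN_AGE_YR = 2.0 / 52.0
#: Admissible window for the Reed1 velocity peak, years.
REED1_PEAK_WINDOW_YR = (0.0, 1.5)
#: Modelling window for the log(BMI) cubic, months (2 weeks to 1.5 years).
BMI_CUBIC_WINDOW_MO = (0.5, 18.0)


# --------------------------------------------------------------------------
# Reed1
# --------------------------------------------------------------------------
def reed1_weight(t, A, B, C, D):
    t = np.asarray(t, dtype=float)
    return A + B * t + C * np.log(t) + D / t


def reed1_velocity(t, B, C, D):
    t = np.asarray(t, dtype=float)
    return B + C / t - D / t**2


def reed1_peak(B, C, D, window=REED1_PEAK_WINDOW_YR):
    """Closed-form (t_peak, PWV, flag) of the Reed1 velocity (vectorized).

    Interior peak t* = 2D/C, PWV = B + C^2/(4D) when C > 0, D > 0 and t*
    falls inside the admissible window; otherwise the velocity is maximised
    on the window boundary and the result flagged 'boundary'.
    """
    B, C, D = np.broadcast_arrays(
        np.asarray(B, dtype=float), np.asarray(C, dtype=float), np.asarray(D, dtype=float)
    )
    scalar = B.ndim == 0
    B, C, D = np.atleast_1d(B), np.atleast_1d(C), np.atleast_1d(D)
    t_peak = np.full(B.shape, np.nan)
    pwv = np.full(B.shape, np.nan)
    flag = np.full(B.shape, "interior", dtype=object)
    interior = (C > 0) & (D > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = np.where(interior, 2.0 * D / np.where(C != 0, C, np.nan), np.nan)
    interior &= (t_star > window[0]) & (t_star <= window[1])
    t_peak[interior] = t_star[interior]
    pwv[interior] = B[interior] + C[interior] ** 2 / (4.0 * D[interior])
    bnd = ~interior
    if np.any(bnd):
        lo = max(window[0], REED1_MIN_AGE_YR)
        v_lo = reed1_velocity(lo, B[bnd], C[bnd], D[bnd])
        v_hi = reed1_velocity(window[1], B[bnd], C[bnd], D[bnd])
        t_peak[bnd] = np.where(v_lo >= v_hi, lo, window[1])
        pwv[bnd] = np.maximum(v_lo, v_hi)
        flag[bnd] = "boundary"
    if scalar:
        return float(t_peak[0]), float(pwv[0]), str(flag[0])
    return t_peak, pwv, flag


@dataclass
class Reed1Fit:
    """Per-sex Reed1 fixed coefficients plus per-child coefficient offsets."""

    fixed: dict[str, np.ndarray]  # sex -> (A, B, C, D)
    children: pd.DataFrame  # child_id, sex, A, B, C, D (per-child curves)
    method: str = "mixed"
    converged: dict[str, bool] = field(default_factory=dict)


def _reed1_design(t):
    return np.column_stack([np.ones_like(t), t, np.log(t), 1.0 / t])


def _check_reed1_ages(t):
    if np.any(t <= 0):
        raise DomainError("Reed1 observations require age > 0 (ln t, 1/t undefined at 0)")


def fit_reed1(
    observations: pd.DataFrame,
    method: str = "mixed",
    min_obs_per_child: int | None = None,
) -> Reed1Fit:
    """Fit the Reed1 model per sex on long-format observations.

    observations: columns child_id, sex, age_yr, weight_kg.  Ages below
    2 weeks are dropped with a logged count; age <= 0 is an error.

    method 'mixed': per-sex linear mixed model on the basis (1, t, ln t,
    1/t) with random intercept and linear term per child (ML).  Children
    need >= 2 observations (default) — offsets are shrunk by the mixed
    model.  If the mixed fit fails, falls back to pooled OLS with zero
    offsets and logs a warning.

    method 'per_child': independent OLS of the full 4-parameter basis per
    child; requires >= 4 observations per child.
    """
    obs = observations.dropna(subset=["age_yr", "weight_kg"]).copy()
    _check_reed1_ages(obs["age_yr"].to_numpy(dtype=float))
    young = obs["age_yr"] < REED1_MIN_AGE_YR
    if young.any():
        log.info("fit_reed1: dropping %d observations younger than 2 weeks", int(young.sum()))
        obs = obs[~young]
    min_obs = min_obs_per_child or (4 if method == "per_child" else 2)
    counts = obs.groupby("child_id")["age_yr"].count()
    keep = counts[counts >= min_obs].index
    obs = obs[obs["child_id"].isin(keep)]
    if obs.empty:
        raise SingularModelError("no children with enough observations for Reed1")

    fixed: dict[str, np.ndarray] = {}
    converged: dict[str, bool] = {}
    child_rows = []
    for sex, g in obs.groupby("sex", observed=True):
        t = g["age_yr"].to_numpy(dtype=float)
        w = g["weight_kg"].to_numpy(dtype=float)
        X = _reed1_design(t)
        if np.unique(t).size < 4 or np.linalg.matrix_rank(X) < 4:
            raise SingularModelError(f"singular Reed1 basis for sex={sex} (too few distinct ages)")
        ids = g["child_id"].to_numpy()
        if method == "per_child":
            for cid in np.unique(ids):
                m = ids == cid
                if np.unique(t[m]).size < 4:
                    continue
                beta, *_ = np.linalg.lstsq(X[m], w[m], rcond=None)
                child_rows.append((cid, sex, *beta))
            beta_pool, *_ = np.linalg.lstsq(X, w, rcond=None)
            fixed[sex] = beta_pool
            converged[sex] = True
            continue
        exog_re = np.column_stack([np.ones_like(t), t])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(w, X, groups=ids, exog_re=exog_re)
                fit = model.fit(reml=False, method="lbfgs", maxiter=200)
            beta = np.asarray(fit.fe_params, dtype=float)
            fixed[sex] = beta
            converged[sex] = bool(fit.converged)
            re = fit.random_effects
            for cid in np.unique(ids):
                b0, b1 = np.asarray(re[cid], dtype=float)[:2]
                child_rows.append((cid, sex, beta[0] + b0, beta[1] + b1, beta[2], beta[3]))
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover - rare
            log.warning("Reed1 mixed fit failed for sex=%s (%s); pooled OLS fallback", sex, exc)
            beta, *_ = np.linalg.lstsq(X, w, rcond=None)
            fixed[sex] = beta
            converged[sex] = False
            for cid in np.unique(ids):
                child_rows.append((cid, sex, *beta))
    children = pd.DataFrame(child_rows, columns=["child_id", "sex", "A", "B", "C", "D"])
    return Reed1Fit(fixed=fixed, children=children, method=method, converged=converged)


def peak_weight_velocity(fit: Reed1Fit, window=REED1_PEAK_WINDOW_YR) -> pd.DataFrame:
    """Per-child (t_peak [years], PWV [kg/year]) from a Reed1 fit."""
    ch = fit.children
    t_peak, pwv, flag = reed1_peak(
        ch["B"].to_numpy(), ch["C"].to_numpy(), ch["D"].to_numpy(), window=window
    )
    return pd.DataFrame(
        {"child_id": ch["child_id"], "sex": ch["sex"], "t_peak_yr": t_peak, "pwv_kg_per_yr": pwv, "flag": flag}
    )


# --------------------------------------------------------------------------
# log(BMI) cubic
# --------------------------------------------------------------------------
@dataclass
class LogBmiCubicFit:
    """Cubic log(BMI) fixed coefficients (per month) plus per-child offsets.

    beta = (b0, b1, b2, b3) for log BMI = b0 + b1*t + b2*t^2 + b3*t^3 with
    t in months; sex_effect is the additive intercept shift for boys.
    Children carry per-child intercept/linear offsets.
    """

    beta: np.ndarray
    sex_effect: float
    children: pd.DataFrame  # child_id, sex, b0_offset, b1_offset
    window: tuple[float, float] = BMI_CUBIC_WINDOW_MO
    converged: bool = True


def fit_logbmi_cubic(observations: pd.DataFrame, window=BMI_CUBIC_WINDOW_MO) -> LogBmiCubicFit:
    """Cubic mixed model on log(BMI), ages in months within [0.5, 18].

    observations: columns child_id, sex, age_mo, bmi.  The cubic is fitted
    on a unit-scaled age internally for conditioning and reported on the
    month scale.  Random intercept and linear term per child, ML.
    """
    obs = observations.dropna(subset=["age_mo", "bmi"]).copy()
    obs = obs[(obs["age_mo"] >= window[0]) & (obs["age_mo"] <= window[1])]
    if np.unique(obs["age_mo"]).size < 4:
        raise SingularModelError("log-BMI cubic needs >= 4 distinct ages in the window")
    if np.any(obs["bmi"] <= 0):
        raise DomainError("nonpositive BMI in log-BMI cubic input")
    scale = window[1]
    u = obs["age_mo"].to_numpy(dtype=float) / scale
    y = np.log(obs["bmi"].to_numpy(dtype=float))
    is_boy = (obs["sex"].astype(str) == "boy").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(u), u, u**2, u**3, is_boy])
    ids = obs["child_id"].to_numpy()
    exog_re = np.column_stack([np.ones_like(u), u])
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=ids, exog_re=exog_re)
            fit = model.fit(reml=False, method="lbfgs", maxiter=200)
        coef = np.asarray(fit.fe_params, dtype=float)
        converged = bool(fit.converged)
        re = fit.random_effects
        rows = []
        sex_of = obs.groupby("child_id")["sex"].first()
        for cid in np.unique(ids):
            b0, b1 = np.asarray(re[cid], dtype=float)[:2]
            rows.append((cid, sex_of[cid], b0, b1 / scale))
    except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover - rare
        log.warning("log-BMI cubic mixed fit failed (%s); pooled OLS fallback", exc)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        converged = False
        sex_of = obs.groupby("child_id")["sex"].first()
        rows = [(cid, sex_of[cid], 0.0, 0.0) for cid in np.unique(ids)]
    beta = np.array([coef[0], coef[1] / scale, coef[2] / scale**2, coef[3] / scale**3])
    children = pd.DataFrame(rows, columns=["child_id", "sex", "b0_offset", "b1_offset"])
    return LogBmiCubicFit(beta=beta, sex_effect=float(coef[4]), children=children, window=window)


def cubic_peak(b1, b2, b3, window=BMI_CUBIC_WINDOW_MO):
    """Interior maximum of b1*t + b2*t^2 + b3*t^3 within the window (vectorized).

    Solves 3*b3*t^2 + 2*b2*t + b1 = 0 and keeps the real root inside the
    window with negative second derivative; NaN when no such root exists
    (flat, monotone, or out-of-window curves).
    """
    b1, b2, b3 = np.broadcast_arrays(
        np.asarray(b1, dtype=float), np.asarray(b2, dtype=float), np.asarray(b3, dtype=float)
    )
    scalar = b1.ndim == 0
    b1, b2, b3 = np.atleast_1d(b1), np.atleast_1d(b2), np.atleast_1d(b3)
    out = np.full(b1.shape, np.nan)
    cubic = np.abs(b3) > 1e-300
    # quadratic-vertex limit when the cubic term vanishes
    quad = ~cubic & (b2 < 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vert = -b1 / (2.0 * b2)
    ok = quad & (vert >= window[0]) & (vert <= window[1])
    out[ok] = vert[ok]
    disc = 4.0 * b2**2 - 12.0 * b3 * b1
    has = cubic & (disc >= 0)
    sq = np.sqrt(np.where(has, disc, np.nan))
    for sign in (+1.0, -1.0):
        with np.errstate(divide="ignore", invalid="ignore"):
            root = (-2.0 * b2 + sign * sq) / (6.0 * b3)
        second = 6.0 * b3 * root + 2.0 * b2
        ok = has & (root >= window[0]) & (root <= window[1]) & (second < 0)
        out[ok] = root[ok]
    if scalar:
        return float(out[0])
    return out


def adiposity_peak(fit: LogBmiCubicFit) -> pd.DataFrame:
    """Per-child (AGEAP [months], BMIAP [kg/m^2]) from the cubic fit.

    AGEAP is the interior maximum of the child's log-BMI cubic; children
    whose curve has no admissible interior maximum get NaN with flag
    'no-peak'.
    """
    ch = fit.children
    b0, b1, b2, b3 = fit.beta
    sexadj = np.where(ch["sex"].astype(str).to_numpy() == "boy", fit.sex_effect, 0.0)
    c0 = b0 + sexadj + ch["b0_offset"].to_numpy()
    c1 = b1 + ch["b1_offset"].to_numpy()
    ageap = cubic_peak(c1, np.full(len(ch), b2), np.full(len(ch), b3), window=fit.window)
    logbmi = c0 + c1 * ageap + b2 * ageap**2 + b3 * ageap**3
    bmiap = np.exp(logbmi)
    flag = np.where(np.isnan(ageap), "no-peak", "interior")
    return pd.DataFrame(
        {"child_id": ch["child_id"], "sex": ch["sex"], "ageap_mo": ageap, "bmiap": bmiap, "flag": flag}
    )
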