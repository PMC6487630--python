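"""Covariate-adjusted association models and Rubin pooling.

Multivariable OLS of adiposity-outcome SDS on growth exposures
(conditional growth variables, 9-level combined-pattern indicators against
the normal/normal reference, or infant trajectory summaries PWV / BMIAP /
AGEAP), with a basic (child age + sex) or main (plus maternal and child
sociodemographic/lifestyle) covariate set, optionally stratified by birth
size with birth weight as an extra covariate.  Confidence intervals and
p-values use the t distribution with residual degrees of freedom.  Results
across multiply imputed datasets are pooled by Rubin's rules with the
Barnard-Rubin small-sample degrees of freedom.  No multiple-testing
correction is applied anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SingularModelError
from .patterns import PATTERN_LEVELS, REFERENCE_PATTERN

#: Covariates of the confounder-adjusted ("main") model beyond age and sex.
MAIN_COVARIATES = [
    "maternal_age",
    "education_low",
    "prepregnancy_bmi",
    "smoking",
    "folic_acid",
    "parity_multi",
    "non_european",
    "breastfed_ever",
]
BASIC_COVARIATES = ["child_age_yr", "sex_boy"]


@dataclass
class AssociationResult:
    outcome: str
    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    df_resid: float
    model: str = ""
    stratum: str = "all"
    pooled: bool = False
    flag: str | None = None

    def to_dict(self):
        return {
            "outcome": self.outcome,
            "exposure": self.term,
            "stratum": self.stratum,
            "model": self.model,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": self.n,
            "pooled": self.pooled,
            "flag": self.flag or "",
        }


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns that QR pivoting marks as linearly dependent."""
    from scipy.linalg import qr

    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return []
    _, _, piv = qr(X, pivoting=True, mode="economic")
    return [names[j] for j in sorted(piv[r:])]


def fit_linear_model(
    data: pd.DataFrame,
    outcome: str,
    exposures: list[str],
    covariates: list[str] | None = None,
    model_tag: str = "",
    stratum: str = "all",
) -> list[AssociationResult]:
    """OLS of ``outcome`` on exposures + covariates over complete rows.

    Returns one AssociationResult per exposure column.  A rank-deficient
    design raises SingularModelError naming the aliased columns.
    """
    covariates = covariates or []
    cols = [outcome] + exposures + covariates
    d = data[cols].dropna()
    n = len(d)
    names = ["intercept"] + exposures + covariates
    X = np.column_stack([np.ones(n)] + [d[c].to_numpy(dtype=float) for c in exposures + covariates])
    y = d[outcome].to_numpy(dtype=float)
    if n < X.shape[1] + 10:
        raise SingularModelError(
            f"model {model_tag!r} for {outcome}: n={n} below parameters+10 ({X.shape[1] + 10})"
        )
    aliased = _find_aliased(X, names)
    if aliased:
        raise SingularModelError(f"rank-deficient design; aliased columns: {aliased}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - X.shape[1]
    sigma2 = resid @ resid / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, df_resid)
    results = []
    for term in exposures:
        j = names.index(term)
        tval = beta[j] / se[j]
        results.append(
            AssociationResult(
                outcome=outcome,
                term=term,
                estimate=float(beta[j]),
                se=float(se[j]),
                ci_low=float(beta[j] - tcrit * se[j]),
                ci_high=float(beta[j] + tcrit * se[j]),
                p=float(2 * stats.t.sf(abs(tval), df_resid)),
                n=n,
                df_resid=float(df_resid),
                model=model_tag,
                stratum=stratum,
            )
        )
    return results


def pattern_indicators(pattern: pd.Series, reference: str = REFERENCE_PATTERN) -> pd.DataFrame:
    """8 indicator columns for the combined pattern vs the reference level.

    Children with a missing pattern get NaN indicators (excluded from fits).
    """
    s = pd.Series(np.asarray(pattern, dtype=object), index=pattern.index)
    out = pd.DataFrame(index=s.index)
    missing = s.isna()
    for level in PATTERN_LEVELS:
        if level == reference:
            continue
        col = (s == level).astype(float)
        col[missing] = np.nan
        out["pat:" + level] = col
    return out


def pattern_model(
    data: pd.DataFrame,
    outcome: str,
    pattern_col: str = "pattern",
    covariates: list[str] | None = None,
    model_tag: str = "pattern-main",
) -> list[AssociationResult]:
    """Combined-pattern contrasts vs normal/normal for one outcome."""
    ind = pattern_indicators(data[pattern_col])
    d = pd.concat([data, ind], axis=1)
    return fit_linear_model(
        d, outcome=outcome, exposures=list(ind.columns), covariates=covariates, model_tag=model_tag
    )


def interaction_test(
    data: pd.DataFrame,
    outcome: str,
    fetal_col: str = "fetal_delta",
    infant_col: str = "infant_delta",
    covariates: list[str] | None = None,
) -> float:
    """Wald p-value for the fetal x infant SDS-change product term.

    The model carries both main effects plus child age and sex (basic
    adjustment) unless another covariate list is supplied.
    """
    covariates = BASIC_COVARIATES if covariates is None else covariates
    d = data.copy()
    if d[fetal_col].dropna().empty or d[infant_col].dropna().empty:
        raise SingularModelError("interaction_test: a growth-change column is entirely missing")
    d["_fx_i"] = d[fetal_col] * d[infant_col]
    res = fit_linear_model(
        d,
        outcome=outcome,
        exposures=["_fx_i"],
        covariates=[fetal_col, infant_col] + covariates,
        model_tag="interaction",
    )[0]
    return res.p


def stratified_infant_models(
    data: pd.DataFrame,
    outcome: str,
    birth_size_col: str = "birth_size",
    exposures: tuple[str, ...] = ("pwv_kg_per_yr", "bmiap", "ageap_mo"),
    covariates: list[str] | None = None,
    min_stratum_n: int = 30,
    model_tag: str = "stratified-main",
) -> list[AssociationResult]:
    """PWV / BMIAP / AGEAP models per birth-size stratum (SGA/AGA/LGA).

    Each exposure enters its own model.  Strata with fewer than
    min_stratum_n complete rows are flagged 'skipped-small-stratum' and not
    fitted.
    """
    results = []
    for stratum in ["SGA", "AGA", "LGA"]:
        sub = data[data[birth_size_col].astype(object) == stratum]
        for expo in exposures:
            if expo not in sub.columns:
                continue
            cols = [outcome, expo] + (covariates or [])
            n_complete = len(sub[cols].dropna())
            if n_complete < min_stratum_n:
                results.append(
                    AssociationResult(
                        outcome=outcome, term=expo, estimate=np.nan, se=np.nan,
                        ci_low=np.nan, ci_high=np.nan, p=np.nan, n=n_complete,
                        df_resid=np.nan, model=model_tag, stratum=stratum,
                        flag="skipped-small-stratum",
                    )
                )
                continue
            res = fit_linear_model(
                sub, outcome=outcome, exposures=[expo], covariates=covariates,
                model_tag=model_tag, stratum=stratum,
            )[0]
            results.append(res)
    return results


# --------------------------------------------------------------------------
# Rubin's rules
# --------------------------------------------------------------------------
def pool_rubin(results: list[AssociationResult]) -> AssociationResult:
    """Pool one estimate across m imputed datasets by Rubin's rules.

    Point estimate is the mean; total variance W + (1 + 1/m) B with W the
    mean within-imputation variance and B the between-imputation variance.
    Degrees of freedom follow the Barnard-Rubin small-sample adjustment.
    """
    if not results:
        raise SingularModelError("pool_rubin needs at least one result")
    keys = {(r.outcome, r.term, r.model, r.stratum) for r in results}
    if len(keys) > 1:
        raise SingularModelError(f"pool_rubin: mismatched result specs {keys}")
    m = len(results)
    if m == 1:
        return replace(results[0], pooled=True)
    est = np.array([r.estimate for r in results])
    w = np.array([r.se**2 for r in results])
    qbar = est.mean()
    W = w.mean()
    B = est.var(ddof=1)
    T = W + (1.0 + 1.0 / m) * B
    se = np.sqrt(T)
    nu_com = float(np.mean([r.df_resid for r in results]))
    if B <= 0 or T <= 0:
        df = nu_com
    else:
        lam = (1.0 + 1.0 / m) * B / T
        df_old = (m - 1) / lam**2
        df_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    tcrit = stats.t.ppf(0.975, df)
    tval = qbar / se if se > 0 else np.inf
    r0 = results[0]
    return AssociationResult(
        outcome=r0.outcome,
        term=r0.term,
        estimate=float(qbar),
        se=float(se),
        ci_low=float(qbar - tcrit * se),
        ci_high=float(qbar + tcrit * se),
        p=float(2 * stats.t.sf(abs(tval), df)),
        n=r0.n,
        df_resid=float(df),
        model=r0.model,
        stratum=r0.stratum,
        pooled=True,
    )


def fit_pooled(datasets: list[pd.DataFrame], fit_fn) -> list[AssociationResult]:
    """Apply ``fit_fn(dataset) -> list[AssociationResult]`` per imputed
    dataset and Rubin-pool matching results."""
    per_ds = [fit_fn(ds) for ds in datasets]
    pooled = []
    for group in zip(*per_ds, strict=True):
        pooled.append(pool_rubin(list(group)))
    return pooled
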