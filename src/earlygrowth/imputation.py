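"""Multiple imputation of missing covariates by chained equations.

Each of m completed datasets comes from an independent chain: missing cells
are initialised by resampling observed values, then each incomplete
covariate is cyclically re-imputed from a regression on all other
covariates — a Bayesian linear model (normal draw of the coefficients,
scaled inverse-chi-square draw of the residual variance) for continuous
covariates, and a logistic model with an asymptotic-normal coefficient
draw followed by Bernoulli sampling for binary ones.  Exposures and
outcomes are never imputed; pass them (if at all) only as complete
auxiliary columns.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError

log = logging.getLogger(__name__)

DEFAULT_BURN_IN = 10
DEFAULT_M = 5
MAX_MISSING_FRACTION = 0.6


def _is_binary(series: pd.Series) -> bool:
    vals = set(pd.unique(series.dropna()))
    return vals <= {0, 1, 0.0, 1.0}


def _draw_continuous(rng, X_obs, y_obs, X_mis):
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    df = max(n - p, 2)
    sigma2 = (resid @ resid) / rng.chisquare(df)
    cov = sigma2 * np.linalg.inv(XtX)
    beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return X_mis @ beta + rng.normal(0.0, np.sqrt(sigma2), size=len(X_mis))

def _draw_binary(rng, X_obs, y_obs, X_mis):
    import statsmodels.api as sm

    try:
        fit = sm.GLM(y_obs, X_obs, family=sm.families.Binomial()).fit(maxiter=50)
        beta_hat = np.asarray(fit.params, dtype=float)
        cov = np.asarray(fit.cov_params(), dtype=float)
        cov = (cov + cov.T) / 2.0 + 1e-10 * np.eye(len(beta_hat))
        beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
        p = expit(X_mis @ beta)
    except (np.linalg.LinAlgError, ValueError):  # separation etc.
        p = np.full(len(X_mis), float(np.mean(y_obs)))
    return (rng.uniform(size=len(X_mis)) < p).astype(float)


def impute_covariates(
    data: pd.DataFrame,
    covariates: list[str] | None = None,
    m: int = DEFAULT_M,
    seed: int | None = None,
    burn_in: int = DEFAULT_BURN_IN,
    max_missing: float = MAX_MISSING_FRACTION,
) -> list[pd.DataFrame]:
    """Return m completed copies of ``data`` (covariate cells only differ).

    covariates defaults to every column of ``data`` with at least one
    missing value; fully observed columns always serve as predictors.
    All columns must be numeric (encode categoricals 0/1 first).
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    covariates = covariates or list(data.columns)
    work_cols = list(data.columns)
    base = data[work_cols].astype(float)
    for col in covariates:
        frac = base[col].isna().mean()
        if base[col].notna().sum() == 0:
            raise ConfigurationError(f"covariate {col!r} has no observed values")
        if frac > max_missing:
            raise ConfigurationError(
                f"covariate {col!r} is {frac:.0%} missing (limit {max_missing:.0%})"
            )
    incomplete = [c for c in covariates if base[c].isna().any()]
    if not incomplete:
        return [data.copy() for _ in range(m)]
    binary = {c: _is_binary(base[c]) for c in incomplete}
    seeds = np.random.SeedSequence(seed).spawn(m)

    out = []
    for chain_seq in seeds:
        rng = np.random.default_rng(chain_seq)
        filled = base.copy()
        for col in incomplete:
            mis = filled[col].isna()
            obs_vals = filled.loc[~mis, col].to_numpy()
            filled.loc[mis, col] = rng.choice(obs_vals, size=int(mis.sum()), replace=True)
        for _ in range(burn_in):
            for col in incomplete:
                mis = base[col].isna().to_numpy()
                predictors = [c for c in work_cols if c != col]
                X = np.column_stack([np.ones(len(filled)), filled[predictors].to_numpy(dtype=float)])
                y = filled[col].to_numpy(dtype=float)
                if binary[col]:
                    draw = _draw_binary(rng, X[~mis], y[~mis], X[mis])
                else:
                    draw = _draw_continuous(rng, X[~mis], y[~mis], X[mis])
                y[mis] = draw
                filled[col] = y
        completed = data.copy()
        for col in incomplete:
            completed[col] = filled[col].to_numpy()
        out.append(completed)
    return out
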