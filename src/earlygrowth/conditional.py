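"""Conditional growth variables: weight independent of all prior weights.

For ordered weight-SDS time points t_1 < ... < t_K, the conditional variable
at t_k is the standardized residual of an OLS regression of SDS_k on an
intercept and SDS_1..SDS_{k-1}, fitted over children with complete data at
t_k and every earlier time point.  By construction it is orthogonal to all
prior SDS, so conditional variables isolate the growth information added in
each interval and can enter regression models jointly.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SingularModelError

#: Canonical time-point order of the weight SDS columns.
SDS_ORDER = ["sds_20w", "sds_30w", "sds_birth", "sds_6mo", "sds_12mo", "sds_24mo"]


def conditional_variables(sds_table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Standardized-residual conditional growth variables.

    Returns a frame with one column ``cond_<name>`` per input column (the
    time-point suffix is kept, e.g. ``cond_6mo``), NaN for children lacking
    the time point or any prior time point.  The first time point is its own
    SDS standardized over the eligible sample.
    """
    cols = columns or [c for c in SDS_ORDER if c in sds_table.columns]
    out = pd.DataFrame(index=sds_table.index)
    X = sds_table[cols].to_numpy(dtype=float)
    for k, col in enumerate(cols):
        eligible = ~np.isnan(X[:, : k + 1]).any(axis=1)
        name = "cond_" + col.removeprefix("sds_")
        res = np.full(len(sds_table), np.nan)
        n_el = int(eligible.sum())
        if n_el < k + 2:
            raise SingularModelError(
                f"conditional variable at {col}: only {n_el} children with complete prior data"
            )
        y = X[eligible, k]
        if k == 0:
            resid = y - y.mean()
        else:
            design = np.column_stack([np.ones(n_el), X[eligible, :k]])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                raise SingularModelError(f"singular prior-weight design at time point {col}")
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ beta
        sd = resid.std(ddof=1)
        if sd <= 1e-12:
            raise SingularModelError(f"degenerate (zero-variance) residuals at time point {col}")
        res[eligible] = resid / sd
        out[name] = res
    return out


def critical_period_model(
    conditional_set: pd.DataFrame,
    outcome_sds: pd.Series,
    covariates: pd.DataFrame | None = None,
    min_n: int = 50,
    model_tag: str = "conditional",
):
    """One linear model per conditional variable: outcome SDS ~ conditional + covariates.

    Returns a list of AssociationResult, one per time point, each fitted on
    that time point's own eligible subsample.  Results with n below min_n
    are flagged unstable.
    """
    from .association import fit_linear_model

    results = []
    outcome_name = getattr(outcome_sds, "name", None) or "outcome"
    for col in conditional_set.columns:
        data = pd.DataFrame({outcome_name: outcome_sds, col: conditional_set[col]})
        if covariates is not None:
            data = pd.concat([data, covariates], axis=1)
        res = fit_linear_model(
            data,
            outcome=outcome_name,
            exposures=[col],
            covariates=list(covariates.columns) if covariates is not None else [],
            model_tag=model_tag,
        )[0]
        if res.n < min_n:
            res.flag = "unstable"
        results.append(res)
    return results
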