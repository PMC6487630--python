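"""Allometric adiposity indices and log-SDS outcome construction.

The height power for each adiposity measure is estimated by regressing
ln(measure) on ln(height); the slope is the power that renders
measure/height^power uncorrelated with height.  Indices use the integer
powers conventional for this cohort's measures: fat mass / height^4 (FMI),
fat-free mass / height^2 (FFMI), visceral and pericardial fat / height^3,
with height in metres.  Skewed outcomes (FMI, visceral and pericardial
indices, liver fat fraction) are natural-log transformed before
standardization to SDS on the analysis sample.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

log = logging.getLogger(__name__)

#: Integer height powers used for the indices.
DEFAULT_POWERS = {"fat_mass": 4, "fat_free_mass": 2, "visceral_fat": 3, "pericardial_fat": 3}

#: Outcomes standardized on the natural-log scale (right-skewed measures).
LOG_TRANSFORMED = ("fmi", "visceral_fat_index", "pericardial_fat_index", "liver_fat_fraction")

OUTCOME_COLUMNS = ("bmi", "fmi", "ffmi", "visceral_fat_index", "pericardial_fat_index", "liver_fat_fraction")


@dataclass
class AllometricPower:
    measure: str
    slope: float
    rounded_power: int
    decorrelation_corr: float
    n: int


def estimate_power(values, heights, measure: str = "measure", min_n: int = 10) -> AllometricPower:
    """Height power from log-log regression of an adiposity measure.

    Returns the OLS slope of ln(value) on ln(height), its nearest-integer
    power, and the residual correlation of value/height^slope with height
    (near zero by construction).
    """
    v = np.asarray(values, dtype=float)
    h = np.asarray(heights, dtype=float)
    ok = ~np.isnan(v) & ~np.isnan(h)
    v, h = v[ok], h[ok]
    if v.size < min_n:
        raise DomainError(f"estimate_power needs >= {min_n} complete observations")
    if np.any(v <= 0) or np.any(h <= 0):
        bad = int(np.sum((v <= 0) | (h <= 0)))
        raise DomainError(f"estimate_power: {bad} nonpositive values/heights")
    lh = np.log(h)
    if np.std(lh) < 1e-12:
        raise DomainError("estimate_power: heights are constant; slope undefined")
    lv = np.log(v)
    slope = float(np.cov(lh, lv, ddof=1)[0, 1] / np.var(lh, ddof=1))
    index = v / h**slope
    corr = float(np.corrcoef(index, h)[0, 1]) if np.std(index) > 0 else 0.0
    return AllometricPower(
        measure=measure,
        slope=slope,
        rounded_power=int(np.rint(slope)),
        decorrelation_corr=corr,
        n=int(v.size),
    )


def standardize(values, log_transform: bool = False) -> np.ndarray:
    """SDS over the non-missing sample (ddof=1); optional natural-log first."""
    v = np.asarray(values, dtype=float).copy()
    ok = ~np.isnan(v)
    if log_transform:
        bad = ok & (v <= 0)
        if bad.any():
            log.warning("standardize: excluding %d nonpositive values before log", int(bad.sum()))
            v[bad] = np.nan
            ok = ~np.isnan(v)
        v[ok] = np.log(v[ok])
    if ok.sum() < 2:
        raise DomainError("standardize needs >= 2 non-missing values")
    sd = v[ok].std(ddof=1)
    if sd <= 0:
        raise DomainError("standardize: zero standard deviation")
    out = np.full(v.shape, np.nan)
    out[ok] = (v[ok] - v[ok].mean()) / sd
    return out


def build_outcomes(
    body: pd.DataFrame,
    powers: dict[str, int] | None = None,
    log_measures: tuple[str, ...] = LOG_TRANSFORMED,
) -> pd.DataFrame:
    """Adiposity outcome panel with SDS columns.

    body: columns height_cm, weight_kg, fat_mass_kg, fat_free_mass_kg,
    visceral_fat_g, pericardial_fat_g, liver_fat_pct (any may be missing
    per child).  Returns the raw indices plus a ``<name>_sds`` column per
    outcome, standardized over each outcome's own analysis sample.
    """
    p = dict(DEFAULT_POWERS)
    if powers:
        p.update(powers)
    h_m = body["height_cm"].to_numpy(dtype=float) / 100.0
    if np.any(h_m[~np.isnan(h_m)] <= 0):
        raise DomainError("nonpositive height in outcome panel")
    out = pd.DataFrame(index=body.index)
    out["bmi"] = body["weight_kg"].to_numpy(dtype=float) / h_m**2
    out["fmi"] = body["fat_mass_kg"].to_numpy(dtype=float) / h_m ** p["fat_mass"]
    out["ffmi"] = body["fat_free_mass_kg"].to_numpy(dtype=float) / h_m ** p["fat_free_mass"]
    out["visceral_fat_index"] = body["visceral_fat_g"].to_numpy(dtype=float) / h_m ** p["visceral_fat"]
    out["pericardial_fat_index"] = body["pericardial_fat_g"].to_numpy(dtype=float) / h_m ** p["pericardial_fat"]
    out["liver_fat_fraction"] = body["liver_fat_pct"].to_numpy(dtype=float)
    for col in OUTCOME_COLUMNS:
        out[col + "_sds"] = standardize(out[col].to_numpy(), log_transform=col in log_measures)
    return out
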