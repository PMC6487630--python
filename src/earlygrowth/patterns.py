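"""Centile-crossing growth-pattern classification.

Weight change between two ages is expressed as the difference in SDS; a
change of more than +0.67 SD (one centile band on a growth chart) is
acceleration, less than -0.67 SD deceleration, anything in between normal
growth.  Fetal (second trimester -> birth) and infant (birth -> last
available infant weight) categories combine into a 9-level pattern with
(normal, normal) as reference.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

#: Centile-crossing threshold on the SDS-change scale (one centile band).
CENTILE_CROSSING_THRESHOLD = 0.67

CATEGORIES = ["deceleration", "normal", "acceleration"]

#: 9 combined fetal x infant levels, ordered as fetal-major.
PATTERN_LEVELS = [f"{f}/{i}" for f in CATEGORIES for i in CATEGORIES]
REFERENCE_PATTERN = "normal/normal"

#: Fallback preference for the infant weight used in birth -> infancy change.
INFANT_FALLBACK_ORDER = [("sds_24mo", "24mo"), ("sds_12mo", "11mo"), ("sds_6mo", "6mo")]


def delta_sds(sds_from, sds_to):
    """SDS change between two ages; missing input propagates."""
    a = np.asarray(sds_from, dtype=float)
    b = np.asarray(sds_to, dtype=float)
    out = b - a
    return out if out.ndim else float(out)


def classify_change(delta, threshold: float = CENTILE_CROSSING_THRESHOLD):
    """deceleration / normal / acceleration from an SDS change.

    The boundary is strict: a change of exactly +-threshold is normal growth.
    """
    d = np.atleast_1d(np.asarray(delta, dtype=float))
    out = np.full(d.shape, None, dtype=object)
    out[d > threshold] = "acceleration"
    out[d < -threshold] = "deceleration"
    out[(d >= -threshold) & (d <= threshold)] = "normal"
    if np.asarray(delta).ndim == 0:
        return out[0]
    return pd.Categorical(out, categories=CATEGORIES)


def select_infant_weight(sds_table: pd.DataFrame) -> pd.DataFrame:
    """Pick the infant weight SDS for the birth -> infancy interval.

    Uses 24-month SDS when available, else the ~12-month visit (tagged
    '11mo'), else 6 months.  Returns a frame with columns 'sds' and
    'source'; both missing when no infant weight exists.
    """
    sds = pd.Series(np.nan, index=sds_table.index, dtype=float)
    source = pd.Series(pd.NA, index=sds_table.index, dtype=object)
    for col, tag in INFANT_FALLBACK_ORDER:
        if col not in sds_table.columns:
            continue
        take = sds.isna() & sds_table[col].notna()
        sds[take] = sds_table.loc[take, col]
        source[take] = tag
    return pd.DataFrame({"sds": sds, "source": source})


def combined_pattern(fetal_category, infant_category):
    """Combine fetal and infant categories into the 9-level pattern."""
    f = pd.Series(np.asarray(fetal_category, dtype=object).ravel())
    i = pd.Series(np.asarray(infant_category, dtype=object).ravel())
    out = f.astype(object) + "/" + i.astype(object)
    out[f.isna() | i.isna()] = None
    cat = pd.Categorical(out, categories=PATTERN_LEVELS)
    if np.asarray(fetal_category).ndim == 0:
        return cat[0] if len(cat) else None
    return cat


def pattern_table(sds_table: pd.DataFrame, threshold: float = CENTILE_CROSSING_THRESHOLD) -> pd.DataFrame:
    """Per-child growth-pattern table from an SDS table.

    sds_table needs columns sds_20w, sds_birth and any of sds_6mo, sds_12mo,
    sds_24mo.  Output columns: fetal_delta, fetal_category, infant_delta,
    infant_category, infant_source, pattern.
    """
    infant = select_infant_weight(sds_table)
    fetal_delta = sds_table["sds_birth"] - sds_table["sds_20w"]
    infant_delta = infant["sds"] - sds_table["sds_birth"]
    out = pd.DataFrame(index=sds_table.index)
    out["fetal_delta"] = fetal_delta
    out["fetal_category"] = classify_change(fetal_delta.to_numpy(), threshold)
    out["infant_delta"] = infant_delta
    out["infant_category"] = classify_change(infant_delta.to_numpy(), threshold)
    out["infant_source"] = infant["source"]
    out["pattern"] = combined_pattern(
        out["fetal_category"].to_numpy(dtype=object), out["infant_category"].to_numpy(dtype=object)
    )
    return out


def pattern_counts(patterns) -> pd.Series:
    """Counts over the 9 combined levels (children with both categories)."""
    return pd.Series(pd.Categorical(patterns, categories=PATTERN_LEVELS)).value_counts().reindex(PATTERN_LEVELS)


def group_shares(counts) -> pd.Series:
    """Percentage share of each group among the classified total."""
    c = pd.Series(counts, dtype=float)
    return 100.0 * c / c.sum()
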