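"""Cohort readers/writers and pipeline configuration.

The wide cohort table is delimited text, one row per child, decimal point
'.', missing values as empty fields.  Readers validate the column
dictionary and check unit plausibility on column medians (weights labelled
kg but with gram-scale magnitudes are a hard error, never silently
converted).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError
from .schema import CATEGORICAL_LEVELS, MANDATORY_COLUMNS, NUMERIC_BOUNDS, OBS_COLUMNS

log = logging.getLogger(__name__)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a wide per-child cohort CSV."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise DomainError(f"cohort file {path} is missing or empty")
    df = pd.read_csv(path)
    if df.empty:
        raise DomainError(f"cohort file {path} contains no data rows")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"cohort file lacks mandatory columns: {missing}")
    known = set(MANDATORY_COLUMNS) | set(NUMERIC_BOUNDS) | set(CATEGORICAL_LEVELS) | {"child_id"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        log.warning("ignoring unknown cohort columns: %s", unknown)
    for col, levels in CATEGORICAL_LEVELS.items():
        if col not in df.columns:
            continue
        vals = set(df[col].dropna().astype(str).unique())
        bad = vals - set(levels)
        if bad:
            raise DomainError(f"column {col!r} has unknown levels {sorted(bad)}; expected {levels}")
    for col, (lo, hi) in NUMERIC_BOUNDS.items():
        if col not in df.columns:
            continue
        series = pd.to_numeric(df[col], errors="coerce")
        med = series.median()
        if pd.notna(med) and not lo <= med <= hi:
            raise DomainError(
                f"column {col!r} has median {med:g}, outside the plausible range "
                f"[{lo}, {hi}] for its documented unit — check units"
            )
        df[col] = series
    return df


def read_observations(path) -> pd.DataFrame:
    """Read the long infant observation table (child_id, sex, age_mo, ...)."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise DomainError(f"observation file {path} is missing or empty")
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"observation file lacks columns: {missing}")
    if df["age_mo"].median() > 40:
        raise DomainError("observation ages implausible for months — check units")
    return df


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (validated before any computation)."""

    outdir: str = "earlygrowth_out"
    seed: int = 0
    # input: either simulate (dict of SimConfig fields) or cohort/observation paths
    simulate: dict | None = None
    cohort_path: str | None = None
    observations_path: str | None = None
    # reference charts: 'internal' fits charts on the cohort itself;
    # 'file' loads external charts from chart_path; 'generating' uses the
    # synthetic generator's true population curves as external charts
    # (only meaningful with a simulate section).
    chart_source: str = "internal"
    chart_path: str | None = None
    fetal_bins: int = 8
    birth_bins: int = 5
    infant_bins: int = 6
    min_per_bin: int = 20
    # thresholds
    centile_threshold: float = 0.67
    sga_percentile: float = 0.05
    lga_percentile: float = 0.95
    # models
    outcomes: tuple[str, ...] = (
        "visceral_fat_index_sds",
        "liver_fat_fraction_sds",
        "pericardial_fat_index_sds",
    )
    imputation_m: int = 5
    imputation_burn_in: int = 10
    trajectory_method: str = "mixed"
    min_stratum_n: int = 30
    run_conditional: bool = True
    run_patterns: bool = True
    run_trajectories: bool = True
    run_stratified: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.simulate is None and self.cohort_path is None:
            raise ConfigurationError("config needs either a simulate section or a cohort_path")
        if self.imputation_m < 1:
            raise ConfigurationError("imputation_m must be >= 1")
        if not 0 < self.sga_percentile < self.lga_percentile < 1:
            raise ConfigurationError("percentile cutoffs must satisfy 0 < sga < lga < 1")
        if self.trajectory_method not in ("mixed", "per_child"):
            raise ConfigurationError("trajectory_method must be 'mixed' or 'per_child'")
        if self.chart_source not in ("internal", "file", "generating"):
            raise ConfigurationError("chart_source must be 'internal', 'file' or 'generating'")
        if self.chart_source == "file" and not self.chart_path:
            raise ConfigurationError("chart_source='file' requires chart_path")
        if self.chart_source == "generating" and self.simulate is None:
            raise ConfigurationError("chart_source='generating' requires a simulate section")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        unknown = {k: v for k, v in raw.items() if k not in known}
        if unknown:
            log.warning("ignoring unknown config keys: %s", sorted(unknown))
        if "outcomes" in kwargs and kwargs["outcomes"] is not None:
            kwargs["outcomes"] = tuple(kwargs["outcomes"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["outcomes"] = list(self.outcomes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
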