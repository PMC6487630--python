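"""Age- and sex-specific reference charts and standard deviation scores.

A :class:`ReferenceChart` stores, per sex (or pooled), an ordered grid of
(age, mean, SD) of the possibly log-transformed measure.  Measurements are
converted to SDS by linear interpolation of the mean and SD between grid
ages; SDS = (transformed value - mean) / SD.  Birth size is classified from
birth-weight SDS against the 5th/95th percentile of the standard normal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ChartRangeError, DomainError

#: z cutoffs for small/large for gestational age (5th and 95th percentile).
SGA_Z_CUTOFF = float(stats.norm.ppf(0.05))
LGA_Z_CUTOFF = float(stats.norm.ppf(0.95))

_POOLED = "all"


def _interp_extend(a, xs, ys):
    """Linear interpolation with linear (edge-slope) extrapolation.

    Inside the grid this is plain linear interpolation; outside, the slope
    of the outermost grid segment is extended, so a chart fitted from
    binned means does not flatten over the first/last half bin.
    """
    out = np.interp(a, xs, ys)
    if len(xs) > 1:
        lo = a < xs[0]
        if np.any(lo):
            s = (ys[1] - ys[0]) / (xs[1] - xs[0])
            out[lo] = ys[0] + s * (a[lo] - xs[0])
        hi = a > xs[-1]
        if np.any(hi):
            s = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            out[hi] = ys[-1] + s * (a[hi] - xs[-1])
    return out


@dataclass
class ReferenceChart:
    """Reference grid used to convert raw measurements to SDS.

    grids maps a sex label ('boy'/'girl', or 'all' when not sex specific)
    to a DataFrame with columns age, mean, sd over strictly increasing ages.
    transform is 'identity' or 'log' (natural log applied before centring).
    """

    measure: str
    axis: str  # 'gestational-weeks' or 'postnatal-months'
    sex_specific: bool
    transform: str = "identity"
    grids: dict[str, pd.DataFrame] = field(default_factory=dict)
    extrapolation_margin: float = 1.0
    #: observed age range of the reference sample per sex; queries are
    #: allowed on this range (plus margin) with constant extrapolation
    #: beyond the outer bin centres.  Defaults to the bin-centre range.
    support: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        if self.transform not in ("identity", "log"):
            raise DomainError(f"unknown transform {self.transform!r}")
        for sex, grid in self.grids.items():
            ages = grid["age"].to_numpy()
            if np.any(np.diff(ages) <= 0):
                raise DomainError(f"chart ages not strictly increasing for sex={sex}")
            if np.any(grid["sd"].to_numpy() <= 0):
                raise DomainError(f"chart SDs must be strictly positive (sex={sex})")

    def _grid_for(self, sex: str | None) -> pd.DataFrame:
        if not self.sex_specific:
            return self.grids[_POOLED]
        if sex not in self.grids:
            raise DomainError(f"chart {self.measure!r} has no grid for sex={sex!r}")
        return self.grids[sex]

    def zscore(self, values, ages, sex=None):
        """SDS of values at ages (vectorized). Missing values/ages give NaN.

        Ages must lie within the grid range extended by the extrapolation
        margin (constant extrapolation); beyond that, ChartRangeError.
        """
        values = np.atleast_1d(np.asarray(values, dtype=float))
        ages = np.broadcast_to(np.atleast_1d(np.asarray(ages, dtype=float)), values.shape).copy()
        out = np.full(values.shape, np.nan)
        if self.sex_specific:
            sex_arr = np.broadcast_to(np.atleast_1d(np.asarray(sex, dtype=object)), values.shape)
            groups = [(s, np.asarray(sex_arr == s)) for s in self.grids]
            unknown = ~np.isin(sex_arr, list(self.grids)) & ~np.isnan(values)
            if np.any(unknown):
                raise DomainError(
                    f"chart {self.measure!r}: unknown sex labels {set(sex_arr[unknown])}"
                )
        else:
            groups = [(_POOLED, np.ones(values.shape, dtype=bool))]
        for s, mask in groups:
            grid = self.grids[s]
            ga = grid["age"].to_numpy()
            a_lo, a_hi = self.support.get(s, (ga[0], ga[-1]))
            lo, hi = a_lo - self.extrapolation_margin, a_hi + self.extrapolation_margin
            a = ages[mask]
            v = values[mask]
            ok = ~np.isnan(v) & ~np.isnan(a)
            if np.any(ok & ((a < lo) | (a > hi))):
                raise ChartRangeError(
                    f"age outside chart range [{lo:g}, {hi:g}] for measure {self.measure!r}"
                )
            mu = _interp_extend(a, ga, grid["mean"].to_numpy())
            sd = np.maximum(_interp_extend(a, ga, grid["sd"].to_numpy()), 1e-12)
            tv = np.where(ok, v, np.nan)
            if self.transform == "log":
                if np.any(tv[ok] <= 0):
                    raise DomainError(f"nonpositive value for log-transformed measure {self.measure!r}")
                tv = np.log(tv)
            z = (tv - mu) / sd
            res = out[mask]
            res[ok] = z[ok]
            out[mask] = res
        return out if np.asarray(values).ndim else float(out[0])

    def invert(self, zscores, ages, sex=None):
        """Raw measurement value corresponding to given SDS (inverse of zscore)."""
        z = np.atleast_1d(np.asarray(zscores, dtype=float))
        ages = np.broadcast_to(np.atleast_1d(np.asarray(ages, dtype=float)), z.shape)
        out = np.full(z.shape, np.nan)
        if self.sex_specific:
            sex_arr = np.broadcast_to(np.atleast_1d(np.asarray(sex, dtype=object)), z.shape)
            groups = [(s, np.asarray(sex_arr == s)) for s in self.grids]
        else:
            groups = [(_POOLED, np.ones(z.shape, dtype=bool))]
        for s, mask in groups:
            grid = self.grids[s]
            ga = grid["age"].to_numpy()
            a = np.asarray(ages[mask], dtype=float)
            mu = _interp_extend(a, ga, grid["mean"].to_numpy())
            sd = np.maximum(_interp_extend(a, ga, grid["sd"].to_numpy()), 1e-12)
            tv = mu + z[mask] * sd
            out[mask] = np.exp(tv) if self.transform == "log" else tv
        return out

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, grid in self.grids.items():
            g = grid.copy()
            g.insert(0, "sex", s)
            lo, hi = self.support.get(s, (grid["age"].iloc[0], grid["age"].iloc[-1]))
            g["age_min"], g["age_max"] = lo, hi
            rows.append(g)
        frame = pd.concat(rows, ignore_index=True)
        frame.insert(0, "measure", self.measure)
        frame["axis"] = self.axis
        frame["transform"] = self.transform
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, extrapolation_margin: float = 1.0) -> "ReferenceChart":
        measure = frame["measure"].iloc[0]
        axis = frame["axis"].iloc[0]
        transform = frame["transform"].iloc[0]
        grids = {}
        support = {}
        for s, g in frame.groupby("sex"):
            grids[str(s)] = g[["age", "mean", "sd"]].sort_values("age").reset_index(drop=True)
            if "age_min" in g.columns:
                support[str(s)] = (float(g["age_min"].iloc[0]), float(g["age_max"].iloc[0]))
        return cls(
            measure=measure,
            axis=axis,
            sex_specific=set(grids) != {_POOLED},
            transform=transform,
            grids=grids,
            extrapolation_margin=extrapolation_margin,
            support=support,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "ReferenceChart":
        return cls.from_frame(pd.read_csv(path), **kw)


def fit_reference(
    sample: pd.DataFrame,
    measure: str,
    axis: str,
    transform: str = "identity",
    n_bins: int = 5,
    sex_specific: bool = False,
    min_per_bin: int = 20,
    extrapolation_margin: float = 1.0,
    bin_edges=None,
) -> ReferenceChart:
    """Build a reference chart from a reference sample.

    sample needs columns 'age' and 'value' (and 'sex' if sex_specific).
    Ages are cut into n_bins quantile bins (or explicit ``bin_edges``,
    which should respect any natural gaps in the visit schedule); each bin
    contributes one grid point at its mean age with the mean and SD
    (ddof=1) of the transformed values.  Bins below min_per_bin, or with
    zero spread, raise an error naming the offending bin.
    """
    df = sample.dropna(subset=["age", "value"])
    if df["age"].nunique() < 2 and n_bins > 1:
        raise DomainError("fit_reference needs at least 2 distinct ages (or n_bins=1)")
    grids: dict[str, pd.DataFrame] = {}
    support: dict[str, tuple] = {}
    groups = df.groupby("sex") if sex_specific else [(_POOLED, df)]
    for sex, g in groups:
        vals = g["value"].to_numpy(dtype=float)
        ages = g["age"].to_numpy(dtype=float)
        if transform == "log":
            if np.any(vals <= 0):
                raise DomainError(f"nonpositive values for log-transformed measure {measure!r}")
            vals = np.log(vals)
        if bin_edges is not None:
            edges = np.unique(np.asarray(bin_edges, dtype=float))
        else:
            edges = np.unique(np.quantile(ages, np.linspace(0, 1, n_bins + 1)))
        nb = max(len(edges) - 1, 1)
        idx = np.clip(np.searchsorted(edges, ages, side="left") - 1, 0, nb - 1)
        rows = []
        for b in range(nb):
            m = idx == b
            if m.sum() == 0:  # empty gap between visit clusters
                continue
            if m.sum() < max(min_per_bin, 2):
                raise DomainError(
                    f"reference bin {b} for measure {measure!r} (sex={sex}) has "
                    f"{int(m.sum())} < {min_per_bin} observations"
                )
            sd = float(np.std(vals[m], ddof=1))
            if sd <= 0:
                raise DomainError(f"zero spread in reference bin {b} for measure {measure!r}")
            rows.append((float(ages[m].mean()), float(vals[m].mean()), sd))
        grid = pd.DataFrame(rows, columns=["age", "mean", "sd"]).sort_values("age")
        grid = grid.reset_index(drop=True)
        grids[str(sex)] = grid
        support[str(sex)] = (float(ages.min()), float(ages.max()))
    return ReferenceChart(
        measure=measure,
        axis=axis,
        sex_specific=sex_specific,
        transform=transform,
        grids=grids,
        extrapolation_margin=extrapolation_margin,
        support=support,
    )


def classify_birth_size(birth_sds, sga_cutoff: float = SGA_Z_CUTOFF, lga_cutoff: float = LGA_Z_CUTOFF):
    """SGA / AGA / LGA from birth-weight SDS (strict inequalities; NaN -> missing)."""
    z = np.atleast_1d(np.asarray(birth_sds, dtype=float))
    out = np.full(z.shape, None, dtype=object)
    out[z < sga_cutoff] = "SGA"
    out[z > lga_cutoff] = "LGA"
    out[(z >= sga_cutoff) & (z <= lga_cutoff)] = "AGA"
    if np.asarray(birth_sds).ndim == 0:
        return out[0]
    return pd.Categorical(out, categories=["SGA", "AGA", "LGA"])
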