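"""Environmental covariates: stage-windowed weather summaries and the W matrix.

Daily weather series are summarized per rice phenological stage (six windows
from emergence to maturity spanning days 0-148 after emergence), tuned to
rice cardinal temperatures for thermal time (GDD). Window summaries are
joined with soil covariates, centered and scaled per column into the
environment x covariate matrix W, and pruned of near-collinear columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "PhenologyCalendar",
    "CardinalTemps",
    "CovariateMatrix",
    "gdd_daily",
    "summarize_stage",
    "build_W",
    "CollinearityFilter",
    "filter_collinear",
]

#: rice phenological stages: (abbreviation, first day, last day), inclusive
DEFAULT_STAGES = (
    ("EM_MAX.TIL", 0, 44),
    ("MAX.TIL_PAN.INIT", 45, 59),
    ("PAN.INIT_PRE.FLW", 60, 74),
    ("PRE.FLW_FLW", 75, 89),
    ("FLW_POST.FLW", 90, 104),
    ("POST.FLW_MAT", 105, 148),
)


@dataclass(frozen=True)
class PhenologyCalendar:
    """Ordered, contiguous phenological windows in days after emergence."""

    stages: tuple = DEFAULT_STAGES

    def __post_init__(self):
        if len(self.stages) != 6:
            raise ConfigError("calendar must have exactly 6 phenological stages")
        prev_end = None
        for abbr, start, end in self.stages:
            if start > end:
                raise ConfigError(f"stage {abbr}: start {start} > end {end}")
            if prev_end is not None and start != prev_end + 1:
                raise ConfigError(f"stage {abbr} is not contiguous with previous")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.stages[0][1], self.stages[-1][2]

    def stage_of(self, day: int) -> str:
        for abbr, start, end in self.stages:
            if start <= day <= end:
                return abbr
        return self.stages[-1][0]  # late-season days fold into maturity


@dataclass(frozen=True)
class CardinalTemps:
    """Rice cardinal temperatures (deg C) for thermal-time accumulation."""

    t_base: float = 10.0
    t_opt: float = 30.0
    t_max: float = 42.0

    def __post_init__(self):
        if not (self.t_base < self.t_opt < self.t_max):
            raise ConfigError("cardinal temperatures must satisfy t_base < t_opt < t_max")


@dataclass
class CovariateMatrix:
    """Centered/scaled environment x covariate matrix with scaling record.

    values      standardized matrix (environments as rows)
    scaling     per-column mean and sd of the raw data
    provenance  column -> {source, base, stage}
    """

    values: pd.DataFrame
    scaling: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def environments(self) -> list:
        return list(self.values.index)

    @property
    def columns(self) -> list:
        return list(self.values.columns)

    def unscale(self) -> pd.DataFrame:
        """Invert standardization back to the raw summaries."""
        raw = self.values * self.scaling["sd"] + self.scaling["mean"]
        return raw


def gdd_daily(t_min, t_max, cardinal: CardinalTemps = CardinalTemps()):
    """Daily growing degree-days by the capped single-triangle average rule.

    Both temperatures are bounded to [t_base, cardinal t_max] before
    averaging; the result max(0, (tmin_c + tmax_c)/2 - t_base) is never
    negative. Accepts scalars or arrays.
    """
    t_min = np.asarray(t_min, dtype=float)
    t_max = np.asarray(t_max, dtype=float)
    if np.any(t_min > t_max + 1e-12):
        raise DataError("gdd_daily requires t_min <= t_max")
    lo, hi = cardinal.t_base, cardinal.t_max
    avg = 0.5 * (np.clip(t_min, lo, hi) + np.clip(t_max, lo, hi))
    out = np.maximum(0.0, avg - cardinal.t_base)
    return float(out) if out.ndim == 0 else out


def summarize_stage(
    weather: pd.DataFrame,
    calendar: PhenologyCalendar = PhenologyCalendar(),
    cardinal: CardinalTemps = CardinalTemps(),
) -> pd.DataFrame:
    """Per-environment stage-window weather covariates.

    ``weather`` is a wide daily table with columns ``location``, ``day`` and
    one column per base variable. Each (variable, stage) pair yields the
    window mean, except GDD (window sum of daily thermal time from
    T2M_MIN/T2M_MAX) and T2M_RANGE (window mean of daily T2M_MAX - T2M_MIN).
    Column ids are ``VAR_STAGE``. Missing days inside a window are an error.
    """
    for c in ("location", "day"):
        if c not in weather.columns:
            raise DataError(f"weather table missing column {c!r}")
    base_vars = [c for c in weather.columns if c not in ("location", "day")]
    if not base_vars:
        raise DataError("weather table has no variable columns")
    has_minmax = {"T2M_MIN", "T2M_MAX"} <= set(base_vars)
    if not has_minmax:
        raise DataError("weather table must contain T2M_MIN and T2M_MAX")
    lo, hi = calendar.span

    rows = {}
    for loc, grp in weather.groupby("location", sort=True):
        grp = grp.sort_values("day").set_index("day")
        days = set(grp.index)
        needed = set(range(lo, hi + 1))
        if not needed <= days:
            missing = sorted(needed - days)
            raise DataError(f"location {loc}: missing days {missing[:5]} in calendar span")
        rec = {}
        for abbr, start, end in calendar.stages:
            win = grp.loc[start:end]
            for v in base_vars:
                rec[f"{v}_{abbr}"] = float(win[v].mean())
            rec[f"T2M_RANGE_{abbr}"] = float((win["T2M_MAX"] - win["T2M_MIN"]).mean())
            rec[f"GDD_{abbr}"] = float(
                np.sum(gdd_daily(win["T2M_MIN"].to_numpy(), win["T2M_MAX"].to_numpy(), cardinal))
            )
        rows[str(loc)] = rec
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "environment"
    return out


def build_W(
    weather_summaries: pd.DataFrame,
    soil: Optional[pd.DataFrame] = None,
) -> CovariateMatrix:
    """Join weather-stage and soil covariates and standardize per column.

    Environments present in the weather summaries but lacking soil data are
    dropped with a warning (the 19 -> 18 site reduction seen with incomplete
    soil extractions). Zero-variance columns are dropped and logged.
    """
    ws = weather_summaries.copy()
    ws.index = ws.index.astype(str)
    if soil is not None:
        so = soil.copy()
        if "location" in so.columns:
            so = so.set_index("location")
        so.index = so.index.astype(str)
        common = [e for e in ws.index if e in set(so.index)]
        missing = [e for e in ws.index if e not in set(so.index)]
        if missing:
            logger.warning("dropping environments without soil data: %s", missing)
        if not common:
            raise DataError("no common environments between weather and soil tables")
        joined = pd.concat([ws.loc[common], so.loc[common]], axis=1)
        soil_cols = set(so.columns)
    else:
        joined = ws
        soil_cols = set()
    if joined.isna().any().any():
        raise DataError("covariate table contains missing values")
    if joined.columns.duplicated().any():
        raise DataError("duplicate covariate column ids")

    sd = joined.std(ddof=1)
    dead = list(sd.index[(sd == 0) | sd.isna()])
    if dead:
        logger.warning("dropping zero-variance covariates: %s", dead)
        joined = joined.drop(columns=dead)
        sd = sd.drop(dead)
    if joined.shape[1] == 0:
        raise DataError("no covariates remain after zero-variance removal")
    mean = joined.mean()
    values = (joined - mean) / sd
    scaling = pd.DataFrame({"mean": mean, "sd": sd})
    prov = {}
    for c in joined.columns:
        if c in soil_cols:
            prov[c] = {"source": "soil", "base": c, "stage": "none"}
        else:
            base, _, stage = c.rpartition("_")
            # stage abbreviations themselves contain underscores; split on
            # the first known stage suffix instead
            for abbr, _, _ in DEFAULT_STAGES:
                if c.endswith("_" + abbr):
                    base, stage = c[: -len(abbr) - 1], abbr
                    break
            prov[c] = {"source": "weather", "base": base, "stage": stage}
    return CovariateMatrix(values=values, scaling=scaling, provenance=prov)


class CollinearityFilter(BaseEstimator, TransformerMixin):
    """Greedy removal of near-collinear columns (|Pearson r| >= threshold).

    Repeatedly drops, among columns involved in an offending pair, the one
    with the largest mean absolute correlation to all remaining columns
    (ties: the later column in input order), until no pair reaches the
    threshold. Deterministic given column order.
    """

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        if not (0.0 < self.threshold <= 1.0):
            raise ConfigError("collinearity threshold must be in (0, 1]")
        if X.shape[1] < 2:
            raise DataError("collinearity filter requires at least 2 columns")
        cols = list(X.columns)
        R = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
        R = np.nan_to_num(R, nan=0.0)
        np.fill_diagonal(R, 0.0)
        A = np.abs(R)
        alive = list(range(len(cols)))
        dropped = []
        while True:
            sub = A[np.ix_(alive, alive)]
            over = sub >= self.threshold
            if not over.any():
                break
            cand = np.where(over.any(axis=1))[0]
            mean_abs = sub[cand].mean(axis=1)
            # argmax with ties resolved to the LATER column in input order
            best = cand[np.lexsort((np.arange(len(cand)), mean_abs))][-1]
            dropped.append(cols[alive[best]])
            del alive[best]
        self.selected_ = [cols[i] for i in alive]
        self.dropped_ = dropped
        if dropped:
            logger.info("collinearity filter dropped %d columns: %s", len(dropped), dropped)
        # post-filter audit, asserted on every run
        keep = [cols.index(c) for c in self.selected_]
        resid = A[np.ix_(keep, keep)]
        self.max_abs_corr_ = float(resid.max()) if len(keep) > 1 else 0.0
        if self.max_abs_corr_ >= self.threshold:  # pragma: no cover
            raise RuntimeError("post-filter audit failed: collinear pair remains")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_]


def filter_collinear(W: CovariateMatrix, threshold: float = 0.95) -> CovariateMatrix:
    """Apply :class:`CollinearityFilter` to a CovariateMatrix."""
    filt = CollinearityFilter(threshold=threshold).fit(W.values)
    keep = filt.selected_
    return CovariateMatrix(
        values=W.values[keep],
        scaling=W.scaling.loc[keep],
        provenance={c: W.provenance.get(c, {}) for c in keep},
    )
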