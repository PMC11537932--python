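"""Evaluation scenarios, Cullis heritability economics and trial reduction.

Four joint-analysis scenarios are compared on the stage-1 BLUEs:

MET      complete multi-environment model, identity GxE covariance
MET_EC   MET with the enviromic kernel Omega structuring the GxE term
WC_MET   MET fitted within each mega-environment cluster (mean +- SD)
OPT_MET  MET on one randomly sampled location per cluster, replicated

Each scenario is costed (genotypes x replicates x price/plot x locations x
years, exact decimal arithmetic) and summarized as Cullis H2 per dollar.
Two reduction figures are computed: the advanced-trial location reduction
and the simulated whole-network trial reduction under one-location-per-
cluster sampling.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError
from .kernels import EnvKernel
from .lmm import cullis_h2, stage2_fit

__all__ = [
    "CostModel",
    "ScenarioResult",
    "run_met",
    "run_met_ec",
    "run_wc_met",
    "run_opt_met",
    "trial_cost",
    "h2_per_dollar",
    "location_reduction",
    "reduction_advanced",
    "reduction_network",
    "reallocation_report",
    "round1",
]


def _dec(x) -> Decimal:
    return x if isinstance(x, Decimal) else Decimal(str(x))


def round1(x) -> float:
    """Round half-up to 1 decimal (report parity for percentages)."""
    return float(_dec(x).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CostModel:
    """Phenotyping / genotyping rates for a trial network."""

    n_genotypes: int
    n_replicates: int
    price_per_plot: Decimal
    n_locations: int
    n_years: int
    price_per_genotyped_line: Decimal = Decimal("6")

    def __post_init__(self):
        object.__setattr__(self, "price_per_plot", _dec(self.price_per_plot))
        object.__setattr__(
            self, "price_per_genotyped_line", _dec(self.price_per_genotyped_line)
        )
        vals = (
            self.n_genotypes,
            self.n_replicates,
            self.price_per_plot,
            self.n_locations,
            self.n_years,
            self.price_per_genotyped_line,
        )
        if any(v <= 0 for v in vals):
            raise ConfigError("all cost-model quantities must be positive")


def trial_cost(cm: CostModel) -> Decimal:
    """Total phenotyping cost: genotypes x reps x price x locations x years."""
    return (
        Decimal(cm.n_genotypes)
        * Decimal(cm.n_replicates)
        * cm.price_per_plot
        * Decimal(cm.n_locations)
        * Decimal(cm.n_years)
    )


def h2_per_dollar(h2: float, cost: Union[Decimal, float]) -> float:
    """Heritability per dollar invested (1/USD)."""
    cost = _dec(cost)
    if cost <= 0:
        raise ConfigError("cost must be positive")
    return float(h2) / float(cost)


@dataclass
class ScenarioResult:
    scenario: str
    h2: float
    h2_sd: Optional[float]  # None for the single-fit scenarios
    cost: Optional[Decimal]
    h2_per_dollar: Optional[float]
    detail: dict

    def __post_init__(self):
        if not (0.0 <= self.h2 <= 1.0):
            raise DataError("H2 must lie in [0, 1]")


def _with_cost(scenario, h2, h2_sd, cost_model, detail) -> ScenarioResult:
    cost = trial_cost(cost_model) if cost_model is not None else None
    return ScenarioResult(
        scenario=scenario,
        h2=float(h2),
        h2_sd=h2_sd,
        cost=cost,
        h2_per_dollar=h2_per_dollar(h2, cost) if cost is not None else None,
        detail=detail,
    )


def _check_blues(blues: pd.DataFrame):
    if blues["genotype"].nunique() < 2:
        raise DataError("scenarios require at least 2 genotypes")


def run_met(blues: pd.DataFrame, cost_model: Optional[CostModel] = None) -> ScenarioResult:
    """Complete multi-environment model with identity GxE."""
    _check_blues(blues)
    fit = stage2_fit(blues, variant="MET")
    h2 = cullis_h2(fit)
    return _with_cost("MET", h2, None, cost_model, {"varcomp": fit.varcomp_, "fit": fit})


def run_met_ec(
    blues: pd.DataFrame, omega: EnvKernel, cost_model: Optional[CostModel] = None
) -> ScenarioResult:
    """MET with the enviromic kernel structuring the GxE covariance."""
    _check_blues(blues)
    kernel = omega.matrix if isinstance(omega, EnvKernel) else omega
    fit = stage2_fit(blues, variant="MET_EC", kernel=kernel)
    h2 = cullis_h2(fit)
    return _with_cost("MET_EC", h2, None, cost_model, {"varcomp": fit.varcomp_, "fit": fit})


def run_wc_met(
    blues: pd.DataFrame,
    assignments: pd.Series,
    cost_model: Optional[CostModel] = None,
) -> ScenarioResult:
    """MET fitted within each cluster; aggregate = unweighted mean +- SD.

    Clusters with fewer than 2 environments cannot support the model and are
    excluded with a warning.
    """
    _check_blues(blues)
    amap = assignments.copy()
    amap.index = amap.index.astype(str)
    per_cluster = {}
    skipped = []
    for c in sorted(amap.unique()):
        locs = list(amap.index[amap == c])
        present = [l for l in locs if l in set(blues["location"].astype(str))]
        if len(present) < 2:
            skipped.append(int(c))
            continue
        fit = stage2_fit(blues, variant="WC", subset=present)
        per_cluster[int(c)] = cullis_h2(fit)
    if skipped:
        warnings.warn(
            f"clusters with a single environment excluded from WC_MET: {skipped}",
            RuntimeWarning,
        )
    if not per_cluster:
        raise DataError("no cluster has enough environments for WC_MET")
    vals = np.array(list(per_cluster.values()))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return _with_cost(
        "WC_MET",
        float(vals.mean()),
        sd,
        cost_model,
        {"per_cluster": per_cluster, "excluded": skipped},
    )


def run_opt_met(
    blues: pd.DataFrame,
    assignments: pd.Series,
    n_reps: int = 10,
    seed: int = 0,
    cost_model: Optional[CostModel] = None,
) -> ScenarioResult:
    """MET on one location sampled per cluster, replicated to avoid bias."""
    _check_blues(blues)
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    amap = assignments.copy()
    amap.index = amap.index.astype(str)
    have = set(blues["location"].astype(str))
    groups = {
        int(c): [l for l in amap.index[amap == c] if l in have]
        for c in sorted(amap.unique())
    }
    if any(len(v) == 0 for v in groups.values()):
        raise DataError("a cluster has no locations present in the BLUE table")
    rng = np.random.default_rng(seed)
    h2s, subsets = [], []
    for _ in range(n_reps):
        subset = [str(rng.choice(v)) for v in groups.values()]
        fit = stage2_fit(blues, variant="OPT", subset=subset)
        h2s.append(cullis_h2(fit))
        subsets.append(subset)
    sd = float(np.std(h2s, ddof=1)) if len(h2s) > 1 else 0.0
    return _with_cost(
        "OPT_MET",
        float(np.mean(h2s)),
        sd,
        cost_model,
        {"replicates": h2s, "subsets": subsets, "seed": seed},
    )


# --------------------------------------------------------------------------
# reduction arithmetic
# --------------------------------------------------------------------------


def location_reduction(n_selected: int, n_total: int) -> dict:
    """Advanced-trial location reduction, both readings.

    reduction_pct     = 100 * (1 - n_selected / n_total)
    retained_share_pct = 100 * n_selected / n_total
    Both rounded half-up to 1 decimal.
    """
    if n_selected < 0 or n_total <= 0 or n_selected > n_total:
        raise ConfigError("need 0 <= n_selected <= n_total with n_total > 0")
    share = Decimal(100) * Decimal(n_selected) / Decimal(n_total)
    return {
        "reduction_pct": round1(Decimal(100) - share),
        "retained_share_pct": round1(share),
    }


def reduction_advanced(n_selected: int, n_total: int) -> float:
    """Location reduction 100 * (1 - n_selected/n_total), to 1 decimal."""
    return location_reduction(n_selected, n_total)["reduction_pct"]


def reduction_network(
    trials_per_location: pd.Series,
    assignments: pd.Series,
    n_iters: int = 10,
    seed: int = 0,
    exact: bool = False,
) -> dict:
    """Simulated whole-network trial reduction.

    Each iteration keeps one location per cluster; the retained historical
    trial counts are summed and the reduction is 100 * (1 - retained/total).
    ``exact=True`` enumerates every possible draw instead of sampling.
    """
    counts = pd.Series(trials_per_location).copy()
    counts.index = counts.index.astype(str)
    amap = assignments.copy()
    amap.index = amap.index.astype(str)
    missing = sorted(set(counts.index) - set(amap.index))
    if missing:
        raise DataError(f"locations without cluster assignment: {missing[:5]}")
    total = float(counts.sum())
    if total <= 0:
        raise DataError("total trial count must be positive")
    groups = [list(amap.index[amap == c]) for c in sorted(amap.unique())]
    if exact:
        retained = [
            sum(counts[l] for l in combo) for combo in itertools.product(*groups)
        ]
        n_draws = len(retained)
    else:
        if n_iters < 1:
            raise ConfigError("n_iters must be >= 1")
        rng = np.random.default_rng(seed)
        retained = [
            sum(counts[str(rng.choice(g))] for g in groups) for _ in range(n_iters)
        ]
        n_draws = n_iters
    retained = np.asarray(retained, dtype=float)
    reductions = 100.0 * (1.0 - retained / total)
    return {
        "mean_reduction_pct": round1(float(reductions.mean())),
        "mean_retained": float(retained.mean()),
        "total": total,
        "per_draw_reduction_pct": [float(r) for r in reductions],
        "n_draws": n_draws,
    }


def reallocation_report(savings, cm: CostModel) -> dict:
    """How saved budget converts into extra plots, genotypes or lines."""
    savings = _dec(savings)
    if savings < 0:
        raise ConfigError("savings must be non-negative")
    plots = int(savings / cm.price_per_plot)
    return {
        "additional_plots": plots,
        "additional_genotypes": plots // cm.n_replicates,
        "additional_genotyped_lines": int(savings / cm.price_per_genotyped_line),
    }
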