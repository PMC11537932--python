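"""End-to-end pipeline: simulate -> BLUEs -> W -> RFE -> kernels -> clusters
-> scenarios -> TPE report, with a checksum manifest for reproducibility."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .clustering import (
    assign_sites,
    choose_k,
    cluster_adjusted_means,
    economic_importance,
    kmeans_fit,
    pca_summary,
    trial_allocation,
    wss_trace,
)
from .covariates import CardinalTemps, PhenologyCalendar, build_W, filter_collinear, summarize_stage
from .exceptions import ConfigError
from .kernels import compare_kernels, env_kernel, yield_kernel
from .lmm import stage1_all_trials
from .scenarios import (
    CostModel,
    location_reduction,
    reduction_network,
    reallocation_report,
    run_met,
    run_met_ec,
    run_opt_met,
    run_wc_met,
    trial_cost,
)
from .selection import rfe_select
from .synthetic import SimConfig, simulate_network

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings and seeds for every stochastic stage of the pipeline."""

    outdir: str = "artifacts"
    seed: int = 0  # master seed for the synthetic network
    # stage toggles
    simulate: bool = True
    # per-stage seeds (explicit so that each stage is independently seeded)
    rfe_seed: int = 101
    kmeans_seed: int = 202
    opt_seed: int = 303
    network_seed: int = 404
    # settings
    collinearity_threshold: float = 0.95
    rfe_folds: int = 5
    rfe_repeats: int = 5
    rfe_trees: int = 500
    k_max: int = 8
    kmeans_n_init: int = 50
    opt_reps: int = 10
    price_per_plot: str = "25"
    price_per_line: str = "6"
    n_replicates: int = 3
    cardinal_t_base: float = 10.0
    cardinal_t_opt: float = 30.0
    cardinal_t_max: float = 42.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown pipeline settings: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of in-memory results.

    Writes every artifact plus manifest.json (checksums, seeds, version)
    into ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save(fn, obj, name, **kw):
        path = out / name
        fn(obj, path, **kw)
        artifacts.append(path)
        return path

    # 1. data ------------------------------------------------------------
    if config.simulate:
        net = simulate_network(SimConfig(seed=config.seed))
        save(io.write_plots, net.plots, "plots.csv")
        save(io.write_weather, net.weather, "weather.csv")
        save(io.write_soil, net.soil, "soil.csv")
        save(io.write_production, net.production, "production.csv")
        save(io.write_json, net.truth.to_json(), "truth.json")
        plots, weather, soil = net.plots, net.weather, net.soil
        production = net.production
        county_profiles = net.county_profiles
        historical = net.historical_trials
    else:
        plots = io.read_plots(out / "plots.csv")
        weather = io.read_weather(out / "weather.csv")
        soil = io.read_soil(out / "soil.csv")
        production = io.read_production(out / "production.csv")
        county_profiles = io.read_matrix(out / "county_profiles.csv")
        historical = io.read_matrix(out / "historical_trials.csv").iloc[:, 0]
    save(io.write_matrix, county_profiles, "county_profiles.csv", index_label="county")
    save(io.write_matrix, historical.to_frame(), "historical_trials.csv")

    # 2. stage-1 BLUEs -----------------------------------------------------
    blues = stage1_all_trials(plots)
    save(io.write_blues, blues, "blues.csv")

    # 3. environmental covariates -----------------------------------------
    cardinal = CardinalTemps(config.cardinal_t_base, config.cardinal_t_opt, config.cardinal_t_max)
    summaries = summarize_stage(weather, PhenologyCalendar(), cardinal)
    W_full = build_W(summaries, soil)
    W = filter_collinear(W_full, threshold=config.collinearity_threshold)
    save(io.write_matrix, W.values, "W.csv")
    save(io.write_json, {c: {"mean": float(m), "sd": float(s)}
                         for c, (m, s) in W.scaling.iterrows()}, "scaling.json")

    # 4. feature selection -------------------------------------------------
    env_response = blues.groupby("location")["blue"].mean()
    rfe = rfe_select(
        W.values,
        env_response,
        folds=config.rfe_folds,
        repeats=config.rfe_repeats,
        seed=config.rfe_seed,
        n_estimators=config.rfe_trees,
    )
    save(io.write_json, rfe.to_json(), "rfe.json")
    W_sel = W.values[rfe.selected]

    # 5. kernels -----------------------------------------------------------
    omega = env_kernel(W_sel)
    omega_y = yield_kernel(blues)
    comparison = compare_kernels(omega, omega_y)
    save(io.write_matrix, omega.matrix, "omega.csv")
    save(io.write_matrix, omega_y.matrix, "omega_yield.csv")
    save(io.write_json, comparison.to_json(), "comparison.json")

    # 6. mega-environment clustering --------------------------------------
    trace = wss_trace(W_sel, config.k_max, seed=config.kmeans_seed, n_init=config.kmeans_n_init)
    k = choose_k(trace)
    clusters = kmeans_fit(W_sel, k, seed=config.kmeans_seed, n_init=config.kmeans_n_init)
    save(io.write_clusters, clusters.assignments, "clusters.csv")
    save(io.write_matrix, clusters.centroids, "centroids.csv", index_label="cluster")
    save(io.write_matrix, trace.to_frame(), "wss.csv", index_label="k")
    pca = pca_summary(W_sel)
    save(io.write_matrix, pca.scores, "pca_scores.csv")
    save(io.write_matrix, pca.loadings, "pca_loadings.csv", index_label="covariate")
    cmeans = cluster_adjusted_means(blues, clusters.assignments)
    save(io.write_matrix, cmeans.rename("adjusted_mean").to_frame(), "cluster_means.csv",
         index_label="cluster")

    # 7. scenarios ---------------------------------------------------------
    n_gen = int(plots["genotype"].nunique())
    n_loc = int(blues["location"].nunique())
    n_years = int(blues["year"].nunique())
    cm_full = CostModel(n_gen, config.n_replicates, Decimal(config.price_per_plot),
                        n_loc, n_years, Decimal(config.price_per_line))
    cm_opt = CostModel(n_gen, config.n_replicates, Decimal(config.price_per_plot),
                       k, n_years, Decimal(config.price_per_line))
    res = {
        "MET": run_met(blues, cm_full),
        "MET_EC": run_met_ec(blues, omega, cm_full),
        "WC_MET": run_wc_met(blues, clusters.assignments, cm_full),
        "OPT_MET": run_opt_met(blues, clusters.assignments, n_reps=config.opt_reps,
                               seed=config.opt_seed, cost_model=cm_opt),
    }
    scen_json = {
        name: {
            "h2": r.h2,
            "h2_sd": r.h2_sd,
            "cost_usd": str(r.cost),
            "h2_per_dollar": r.h2_per_dollar,
        }
        for name, r in res.items()
    }
    save(io.write_json, scen_json, "scenarios.json")

    # 8. reductions --------------------------------------------------------
    adv = location_reduction(k, n_loc)
    network = reduction_network(historical, clusters.assignments,
                                n_iters=config.opt_reps, seed=config.network_seed)
    savings = trial_cost(cm_full) - trial_cost(cm_opt)
    realloc = reallocation_report(savings, cm_full)
    reductions = {
        "advanced": adv,
        "network": {kk: vv for kk, vv in network.items() if kk != "per_draw_reduction_pct"},
        "savings_usd": str(savings),
        "reallocation": realloc,
    }
    save(io.write_json, reductions, "reductions.json")

    # 9. TPE delimitation --------------------------------------------------
    scale = W.scaling.loc[[c for c in rfe.selected if c in W.scaling.index]]
    prof = county_profiles[scale.index]
    prof_std = (prof - scale["mean"]) / scale["sd"]
    tpe_trace = wss_trace(prof_std, config.k_max, seed=config.kmeans_seed,
                          n_init=config.kmeans_n_init)
    tpe_k = choose_k(tpe_trace)
    tpe = kmeans_fit(prof_std, tpe_k, seed=config.kmeans_seed, n_init=config.kmeans_n_init)
    econ = economic_importance(production, tpe.assignments)
    site_tpe = assign_sites(W_sel, tpe.centroids)
    trials_pct = trial_allocation(historical, site_tpe)
    allocation = {
        "k_tpe": int(tpe_k),
        "production_share_pct": {int(c): float(v) for c, v in econ.items()},
        "trial_share_pct": {int(c): float(v) for c, v in trials_pct.items()},
        "site_assignment": {s: int(c) for s, c in site_tpe.items()},
    }
    save(io.write_json, allocation, "allocation.json")

    # manifest -------------------------------------------------------------
    manifest = {
        "version": "0.1.0",
        "seeds": {
            "simulate": config.seed,
            "rfe": config.rfe_seed,
            "kmeans": config.kmeans_seed,
            "opt": config.opt_seed,
            "network": config.network_seed,
        },
        "settings": {kk: vv for kk, vv in asdict(config).items()},
        "artifacts": {p.name: io.file_sha256(p) for p in sorted(set(artifacts))},
    }
    io.write_json(manifest, out / "manifest.json")

    return {
        "blues": blues,
        "W": W,
        "rfe": rfe,
        "omega": omega,
        "omega_yield": omega_y,
        "comparison": comparison,
        "clusters": clusters,
        "wss_trace": trace,
        "cluster_means": cmeans,
        "scenarios": res,
        "reductions": reductions,
        "allocation": allocation,
        "tpe": tpe,
        "manifest": manifest,
    }
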