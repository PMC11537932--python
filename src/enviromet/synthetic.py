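"""Synthetic multi-environment rice trial networks with known ground truth.

The generator emulates the structure of an advanced-line rice MET: 25
genotypes tested over 2 years (9 in year 1, all 25 in year 2, the 9 common),
18 locations grouped into 5 climate/soil archetypes, RCBD trials with 3
blocks on a serpentine-filled row x column grid, daily weather per location,
soil tables, skewed county production shares, and a 10-year historical
trial-count table.

Yields follow a linear reaction norm: the location main effect and half of
the GxE variance are driven by a small set of informative environmental
covariates (stage-windowed dew point, minimum temperature, temperature
range, thermal time, plus soil TCEQ and SILT); genotype, block, row, column
and residual effects are i.i.d. Gaussian. The planted parameters are
returned as GroundTruth so that recovery can be tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import covariates as cov
from .exceptions import ConfigError, DataError

__all__ = [
    "ClusterArchetype",
    "SimConfig",
    "GroundTruth",
    "NetworkData",
    "default_cluster_spec",
    "simulate_weather",
    "simulate_soil",
    "simulate_network",
    "simulate_met_blues",
]

# base (flat) daily profiles for the simulated weather variables; T2M_MIN and
# T2M_MAX are built from the T2M center and half-range so that
# min <= mean <= max holds by construction
BASE_WEATHER = {
    "T2M": 24.0,
    "T2MDEW": 17.0,
    "RH2M": 78.0,
    "PRECTOTCORR": 6.0,
    "ALLSKY_SFC_SW_DWN": 21.0,
    "ALLSKY_SFC_LW_DWN": 38.0,
    "WS2M": 2.5,
    "GWETTOP": 0.60,
    "GWETROOT": 0.55,
    "GWETPROF": 0.50,
    "EVPTRNS": 3.5,
    "EVLAND": 4.0,
    "QV2M": 14.0,
    "PS": 101.0,
    "CLRSKY_SFC_SW_DWN": 26.0,
}
BASE_HALF_RANGE = 5.0  # half of the daily T2M_MAX - T2M_MIN spread, deg C

DAILY_SD = {
    "T2M": 1.5,
    "T2MDEW": 2.0,
    "HALF_RANGE": 0.5,
    "RH2M": 5.0,
    "PRECTOTCORR": 3.0,
    "ALLSKY_SFC_SW_DWN": 3.0,
    "ALLSKY_SFC_LW_DWN": 2.0,
    "WS2M": 0.6,
    "GWETTOP": 0.05,
    "GWETROOT": 0.04,
    "GWETPROF": 0.03,
    "EVPTRNS": 0.6,
    "EVLAND": 0.7,
    "QV2M": 1.0,
    "PS": 0.3,
    "CLRSKY_SFC_SW_DWN": 1.5,
}

SOIL_BASE = {
    "TCEQ": 30.0,
    "SILT": 40.0,
    "CLAY": 28.0,
    "SAND": 32.0,
    "PHAQ": 6.3,
    "ORGC": 12.0,
    "TOTN": 1.4,
    "CECSOL": 18.0,
    "BDFI": 1.35,
    "ELCO": 0.4,
    "AWCH": 0.16,
}
SOIL_JITTER = {k: 0.06 * v for k, v in SOIL_BASE.items()}

#: informative axes: covariate id -> (driver variable, stage, archetype
#: separation in raw units, within-cluster jitter SD). GDD is driven through
#: the window's mean temperature; soil axes have stage None.
INFORMATIVE_AXES = {
    "T2MDEW_FLW_POST.FLW": ("T2MDEW", "FLW_POST.FLW", 4.0, 1.0),
    "T2MDEW_PRE.FLW_FLW": ("T2MDEW", "PRE.FLW_FLW", 4.0, 1.0),
    "T2MDEW_PAN.INIT_PRE.FLW": ("T2MDEW", "PAN.INIT_PRE.FLW", 4.0, 1.0),
    "T2M_MIN_MAX.TIL_PAN.INIT": ("T2M_MIN", "MAX.TIL_PAN.INIT", 4.0, 1.0),
    "GDD_PRE.FLW_FLW": ("T2M", "PRE.FLW_FLW", 3.0, 0.75),
    "T2M_RANGE_MAX.TIL_PAN.INIT": ("T2M_RANGE", "MAX.TIL_PAN.INIT", 4.0, 1.0),
    "TCEQ": ("TCEQ", None, 12.0, 3.0),
    "SILT": ("SILT", None, 8.0, 2.0),
}

# archetype pattern on the informative axes: a shared climate gradient
# (distinct levels per archetype, so every informative axis correlates with
# the archetype's yield level) plus Hadamard-sign axis-specific deviations
# (so no two axes are collinear and k-means separation is multi-axis)
_GRADIENT = np.array([1.0, 0.5, 0.0, -0.5, -1.0])
_DEVIATION_SIGNS = np.array(
    [
        [1, 1, 1, 1, 1, 1, 1, 1],
        [1, -1, 1, -1, 1, -1, 1, -1],
        [1, 1, -1, -1, 1, 1, -1, -1],
        [1, -1, -1, 1, 1, -1, -1, 1],
        [-1, 1, 1, -1, -1, 1, 1, -1],
    ],
    dtype=float,
)
_ARCHETYPE_PATTERN = _GRADIENT[:, None] + 0.5 * _DEVIATION_SIGNS


@dataclass(frozen=True)
class ClusterArchetype:
    """Climate/soil archetype for one mega-environment."""

    cluster: int
    members: tuple
    weather_offsets: Mapping  # (variable, stage) -> raw-unit offset
    soil_offsets: Mapping  # soil covariate -> raw-unit offset


def default_cluster_spec(n_locations: int = 18, n_clusters: int = 5) -> tuple:
    """Archetypes over n_locations with near-equal membership."""
    if n_clusters > _ARCHETYPE_PATTERN.shape[0]:
        raise ConfigError("at most 5 default archetypes are defined")
    if n_clusters > n_locations:
        raise ConfigError("more clusters than locations")
    locs = [f"L{i + 1:02d}" for i in range(n_locations)]
    sizes = np.full(n_clusters, n_locations // n_clusters)
    sizes[: n_locations % n_clusters] += 1
    spec = []
    start = 0
    axes = list(INFORMATIVE_AXES.items())
    for c in range(n_clusters):
        members = tuple(locs[start : start + sizes[c]])
        start += sizes[c]
        woff, soff = {}, {}
        for j, (name, (var, stage, sep, _)) in enumerate(axes):
            val = sep * _ARCHETYPE_PATTERN[c, j]
            if stage is None:
                soff[var] = val
            else:
                woff[(var, stage)] = val
        spec.append(
            ClusterArchetype(cluster=c + 1, members=members, weather_offsets=woff, soil_offsets=soff)
        )
    return tuple(spec)


def _default_var_components() -> dict:
    return {
        "genotype": 250_000.0,
        "gxe": 60_000.0,
        "block": 40_000.0,
        "row": 22_500.0,
        "col": 22_500.0,
        "residual": 180_000.0,
    }


def _default_informative() -> tuple:
    return tuple((name, 300.0) for name in INFORMATIVE_AXES)


@dataclass
class SimConfig:
    """Study conditions for the synthetic trial network."""

    n_genotypes: int = 25
    n_genotypes_year1: int = 9
    n_locations: int = 18
    n_years: int = 2
    n_blocks: int = 3
    field_rows: int = 15
    field_cols: int = 5
    cluster_spec: Optional[tuple] = None  # filled from default_cluster_spec
    var_components: dict = field(default_factory=_default_var_components)
    informative_covariates: tuple = field(default_factory=_default_informative)
    seed: int = 0
    # yield-model extras
    mu: float = 8_800.0
    year_effects: Optional[tuple] = None  # fixed kg/ha offsets per year
    loc_noise_sd: float = 150.0  # location main effect not explained by ECs
    ge_structured_share: float = 0.5  # share of sigma2_ge on the reaction norm
    # network extras
    extra_location_without_soil: bool = False
    n_counties: int = 71
    county_share_alpha: float = 0.35
    historical_trials_total: int = 829

    def __post_init__(self):
        if min(self.n_genotypes, self.n_locations, self.n_years, self.n_blocks) < 1:
            raise ConfigError("all design dimensions must be positive")
        if self.n_genotypes_year1 > self.n_genotypes:
            raise ConfigError("n_genotypes_year1 cannot exceed n_genotypes")
        if self.n_genotypes_year1 < 1:
            raise ConfigError("n_genotypes_year1 must be positive")
        if any(v < 0 for v in self.var_components.values()):
            raise ConfigError("variance components must be non-negative")
        if self.field_rows * self.field_cols < self.n_genotypes * self.n_blocks:
            raise ConfigError("field grid too small for genotypes x blocks")
        if not (0.0 <= self.ge_structured_share <= 1.0):
            raise ConfigError("ge_structured_share must be in [0, 1]")
        if self.cluster_spec is None:
            self.cluster_spec = default_cluster_spec(self.n_locations)
        seen = [m for a in self.cluster_spec for m in a.members]
        if sorted(seen) != sorted(set(seen)) or len(seen) != self.n_locations:
            raise ConfigError("every location must belong to exactly one cluster")
        if self.year_effects is None:
            self.year_effects = tuple(300.0 * i for i in range(self.n_years))
        elif len(self.year_effects) != self.n_years:
            raise ConfigError("year_effects must have one entry per year")

    @property
    def genotypes(self) -> list:
        return [f"G{i + 1:02d}" for i in range(self.n_genotypes)]

    @property
    def locations(self) -> list:
        return [m for a in self.cluster_spec for m in a.members]

    @property
    def years(self) -> list:
        return [2021 + i for i in range(self.n_years)]


@dataclass
class GroundTruth:
    """Planted parameters enabling recovery tests."""

    genotype_effects: pd.Series
    location_effects: pd.Series
    ge: pd.DataFrame  # genotype x location interaction effects
    var_components: dict
    informative_covariates: list
    location_clusters: pd.Series
    county_clusters: pd.Series
    true_window_means: pd.DataFrame  # location x informative covariate, raw units
    seed: int

    def to_json(self) -> str:
        payload = {
            "genotype_effects": self.genotype_effects.to_dict(),
            "location_effects": self.location_effects.to_dict(),
            "ge": {g: row.to_dict() for g, row in self.ge.iterrows()},
            "var_components": self.var_components,
            "informative_covariates": list(self.informative_covariates),
            "location_clusters": {k: int(v) for k, v in self.location_clusters.items()},
            "county_clusters": {k: int(v) for k, v in self.county_clusters.items()},
            "true_window_means": {
                loc: row.to_dict() for loc, row in self.true_window_means.iterrows()
            },
            "seed": int(self.seed),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class NetworkData:
    """Everything the downstream pipeline consumes, plus the truth."""

    plots: pd.DataFrame
    weather: pd.DataFrame
    soil: pd.DataFrame
    production: pd.DataFrame
    county_profiles: pd.DataFrame
    historical_trials: pd.Series
    truth: GroundTruth


# --------------------------------------------------------------------------
# weather / soil / profiles
# --------------------------------------------------------------------------


def simulate_weather(
    location: str,
    offsets: Mapping,
    n_days: int = 149,
    seed: int = 0,
    daily_sd: Optional[Mapping] = None,
    calendar: cov.PhenologyCalendar = cov.PhenologyCalendar(),
) -> pd.DataFrame:
    """Daily weather for one location from archetype offsets.

    ``offsets`` maps (variable, stage) to a raw-unit shift; supported special
    variables are T2M (shifts the daily center), T2M_MIN (shifts the minimum)
    and T2M_RANGE (widens the min-max spread). With ``daily_sd`` zeroed the
    series is piecewise constant at the archetype means. ``n_days`` must
    cover the full phenology calendar (149 days: 0 through 148 inclusive).
    """
    if n_days < calendar.span[1] + 1:
        raise ConfigError(f"n_days must cover the full season (>= {calendar.span[1] + 1})")
    sd = dict(DAILY_SD)
    if daily_sd is not None:
        sd.update(daily_sd)
    rng = np.random.default_rng(seed)
    days = np.arange(n_days)
    stages = np.array([calendar.stage_of(int(d)) for d in days])

    def off(var):
        return np.array([offsets.get((var, s), 0.0) for s in stages])

    center = BASE_WEATHER["T2M"] + off("T2M") + rng.normal(0, sd["T2M"], n_days)
    half = BASE_HALF_RANGE + 0.5 * off("T2M_RANGE") + rng.normal(0, sd["HALF_RANGE"], n_days)
    half = np.maximum(half, 0.25)
    t_min = center - half + off("T2M_MIN")
    t_max = center + half
    t_max = np.maximum(t_max, t_min)  # guard extreme offsets
    t2m = 0.5 * (t_min + t_max)

    out = pd.DataFrame({"location": location, "day": days})
    out["T2M"] = t2m
    out["T2M_MIN"] = t_min
    out["T2M_MAX"] = t_max
    for var, base in BASE_WEATHER.items():
        if var == "T2M":
            continue
        out[var] = base + off(var) + rng.normal(0, sd[var], n_days)
    return out


def simulate_soil(location: str, soil_offsets: Mapping, seed: int = 0) -> dict:
    """Soil covariates (one row) for a location: base + archetype + jitter."""
    rng = np.random.default_rng(seed)
    rec = {"location": location}
    for var, base in SOIL_BASE.items():
        rec[var] = base + soil_offsets.get(var, 0.0) + rng.normal(0, SOIL_JITTER[var])
    return rec


def _site_offsets(archetype: ClusterArchetype, rng: np.random.Generator):
    """Archetype offsets plus within-cluster site jitter on informative axes."""
    woff = dict(archetype.weather_offsets)
    soff = dict(archetype.soil_offsets)
    for name, (var, stage, _, jit) in INFORMATIVE_AXES.items():
        z = rng.normal(0.0, jit)
        if stage is None:
            soff[var] = soff.get(var, 0.0) + z
        else:
            woff[(var, stage)] = woff.get((var, stage), 0.0) + z
    return woff, soff


def _expected_axis_value(name: str, woff: Mapping, soff: Mapping,
                         calendar: cov.PhenologyCalendar) -> float:
    """Expected raw covariate value for an informative axis (no daily noise)."""
    var, stage, _, _ = INFORMATIVE_AXES[name]
    if stage is None:
        return SOIL_BASE[var] + soff.get(var, 0.0)
    o = lambda v: woff.get((v, stage), 0.0)
    if var == "T2MDEW":
        return BASE_WEATHER["T2MDEW"] + o("T2MDEW")
    if var == "T2M_MIN":
        return BASE_WEATHER["T2M"] + o("T2M") - BASE_HALF_RANGE - 0.5 * o("T2M_RANGE") + o("T2M_MIN")
    if var == "T2M_RANGE":
        return 2.0 * BASE_HALF_RANGE + o("T2M_RANGE") - o("T2M_MIN")
    if var == "T2M":  # GDD driver: window sum of (mean temp - t_base)
        n_days = [e - s + 1 for a, s, e in calendar.stages if a == stage][0]
        return n_days * (BASE_WEATHER["T2M"] + o("T2M") + 0.5 * o("T2M_MIN") - 10.0)
    raise ConfigError(f"no expectation rule for axis driver {var}")  # pragma: no cover


# --------------------------------------------------------------------------
# full network
# --------------------------------------------------------------------------


def _serpentine(index: int, n_cols: int) -> tuple[int, int]:
    r, c = divmod(index, n_cols)
    return r, (n_cols - 1 - c) if r % 2 else c


def simulate_network(config: SimConfig = SimConfig()) -> NetworkData:
    """Generate the full synthetic MET: plots, weather, soil, production, truth.

    Identical configs (including seed) give byte-identical tables.
    """
    ss = np.random.SeedSequence(config.seed)
    keys = (
        "sites",
        "genetics",
        "weather",
        "soil",
        "plots",
        "production",
        "counties",
        "history",
    )
    rngs = {k: np.random.default_rng(s) for k, s in zip(keys, ss.spawn(len(keys)))}
    calendar = cov.PhenologyCalendar()
    vc = {**_default_var_components(), **config.var_components}

    # --- per-location offsets and truth ---------------------------------
    axes = list(INFORMATIVE_AXES)
    loc_clusters, site_woff, site_soff = {}, {}, {}
    for arch in config.cluster_spec:
        for loc in arch.members:
            loc_clusters[loc] = arch.cluster
            site_woff[loc], site_soff[loc] = _site_offsets(arch, rngs["sites"])
    locations = config.locations
    twm = pd.DataFrame(
        {
            name: [
                _expected_axis_value(name, site_woff[l], site_soff[l], calendar)
                for l in locations
            ]
            for name in axes
        },
        index=locations,
    )

    # standardized informative covariates drive the yield model
    eff = dict(config.informative_covariates)
    unknown = [k for k in eff if k not in axes]
    if unknown:
        raise ConfigError(f"informative covariates without generator axes: {unknown}")
    if len(locations) > 1:
        x_std = (twm - twm.mean()) / twm.std(ddof=1).replace(0.0, 1.0)
    else:
        x_std = twm * 0.0

    loc_eff = pd.Series(0.0, index=locations)
    for name, tau in eff.items():
        loc_eff = loc_eff + tau * x_std[name]
    loc_eff = loc_eff + rngs["sites"].normal(0.0, config.loc_noise_sd, len(locations))

    genotypes = config.genotypes
    g_eff = pd.Series(
        rngs["genetics"].normal(0.0, np.sqrt(vc["genotype"]), len(genotypes)),
        index=genotypes,
    )
    n_axes = max(len(eff), 1)
    slopes = rngs["genetics"].normal(0.0, np.sqrt(1.0 / n_axes), (len(genotypes), n_axes))
    s2_ge = vc["gxe"]
    rho = config.ge_structured_share if eff else 0.0
    xs = x_std[list(eff)].to_numpy() if eff else np.zeros((len(locations), 1))
    ge = np.sqrt(rho * s2_ge) * (slopes[:, : xs.shape[1]] @ xs.T)
    ge = ge + rngs["genetics"].normal(0.0, np.sqrt((1.0 - rho) * s2_ge), ge.shape)
    ge = pd.DataFrame(ge, index=genotypes, columns=locations)

    # --- weather and soil tables ----------------------------------------
    wparts = []
    soil_rows = []
    wseeds = np.random.SeedSequence(int(rngs["weather"].integers(2**31))).spawn(len(locations))
    sseeds = np.random.SeedSequence(int(rngs["soil"].integers(2**31))).spawn(len(locations) + 1)
    for loc, wsd, ssd in zip(locations, wseeds, sseeds):
        wparts.append(
            simulate_weather(loc, site_woff[loc], n_days=149, seed=wsd, calendar=calendar)
        )
        soil_rows.append(simulate_soil(loc, site_soff[loc], seed=ssd))
    if config.extra_location_without_soil:
        # a 19th site with weather but no soil record, to exercise the
        # weather/soil join reduction
        loc = f"L{len(locations) + 1:02d}"
        arch = config.cluster_spec[0]
        woff, _ = _site_offsets(arch, rngs["sites"])
        wparts.append(simulate_weather(loc, woff, n_days=149, seed=sseeds[-1], calendar=calendar))
    weather = pd.concat(wparts, ignore_index=True)
    soil = pd.DataFrame(soil_rows)

    # --- plot table ------------------------------------------------------
    year1 = genotypes[: config.n_genotypes_year1]
    rows = []
    rng_p = rngs["plots"]
    for yi, year in enumerate(config.years):
        gset = year1 if yi == 0 and config.n_years > 1 else genotypes
        for loc in locations:
            blk_eff = rng_p.normal(0.0, np.sqrt(vc["block"]), config.n_blocks)
            row_eff = rng_p.normal(0.0, np.sqrt(vc["row"]), config.field_rows)
            col_eff = rng_p.normal(0.0, np.sqrt(vc["col"]), config.field_cols)
            idx = 0
            for b in range(config.n_blocks):
                order = list(gset)
                rng_p.shuffle(order)
                for g in order:
                    r, c = _serpentine(idx, config.field_cols)
                    y = (
                        config.mu
                        + config.year_effects[yi]
                        + g_eff[g]
                        + loc_eff[loc]
                        + ge.at[g, loc]
                        + blk_eff[b]
                        + row_eff[r]
                        + col_eff[c]
                        + rng_p.normal(0.0, np.sqrt(vc["residual"]))
                    )
                    rows.append((g, loc, year, b + 1, r, c, y))
                    idx += 1
    plots = pd.DataFrame(
        rows,
        columns=["genotype", "location", "year", "replicate", "row", "column", "yield"],
    )

    # --- counties: production shares and environmental profiles ----------
    n_arch = len(config.cluster_spec)
    counties = [f"C{i + 1:02d}" for i in range(config.n_counties)]
    county_cluster = {c: config.cluster_spec[i % n_arch].cluster for i, c in enumerate(counties)}
    shares = rngs["production"].dirichlet(np.full(config.n_counties, config.county_share_alpha))
    shares = shares / shares.sum()
    production = pd.DataFrame(
        {
            "county": counties,
            "production_share": shares,
            "cluster": [county_cluster[c] for c in counties],
        }
    )
    cseeds = np.random.SeedSequence(int(rngs["counties"].integers(2**31))).spawn(
        2 * config.n_counties
    )
    prof_w, prof_s = [], []
    arch_by_id = {a.cluster: a for a in config.cluster_spec}
    for i, county in enumerate(counties):
        arch = arch_by_id[county_cluster[county]]
        woff, soff = _site_offsets(arch, rngs["counties"])
        prof_w.append(
            simulate_weather(county, woff, n_days=149, seed=cseeds[2 * i], calendar=calendar)
        )
        prof_s.append(simulate_soil(county, soff, seed=cseeds[2 * i + 1]))
    cw = pd.concat(prof_w, ignore_index=True)
    summaries = cov.summarize_stage(cw, calendar=calendar)
    csoil = pd.DataFrame(prof_s).set_index("location")
    csoil.index.name = "environment"
    county_profiles = pd.concat([summaries, csoil.loc[summaries.index]], axis=1)

    # --- historical trial counts (10-year network) ------------------------
    w = rngs["history"].dirichlet(np.full(len(locations), 0.3))
    counts = np.maximum(1, np.round(w * config.historical_trials_total).astype(int))
    historical = pd.Series(counts, index=locations, name="n_trials")

    truth = GroundTruth(
        genotype_effects=g_eff,
        location_effects=loc_eff,
        ge=ge,
        var_components=vc,
        informative_covariates=list(eff),
        location_clusters=pd.Series(loc_clusters).loc[locations],
        county_clusters=pd.Series(county_cluster),
        true_window_means=twm,
        seed=config.seed,
    )
    return NetworkData(
        plots=plots,
        weather=weather,
        soil=soil,
        production=production,
        county_profiles=county_profiles,
        historical_trials=historical,
        truth=truth,
    )


# --------------------------------------------------------------------------
# direct stage-2 simulation (for REML recovery tests)
# --------------------------------------------------------------------------


def simulate_met_blues(
    n_genotypes: int = 25,
    n_genotypes_year1: int = 9,
    n_locations: int = 18,
    n_years: int = 2,
    sigma2_g: float = 250_000.0,
    sigma2_ge: float = 60_000.0,
    sigma2_e: float = 75_000.0,
    mu: float = 8_800.0,
    kernel: Optional[pd.DataFrame] = None,
    seed: int = 0,
):
    """Simulate trial-level BLUEs directly from the multi-trial model.

    GxE is i.i.d. per genotype x location, or kernel-structured when an
    environment kernel is supplied. Returns (blues, truth dict).
    """
    if n_genotypes_year1 > n_genotypes:
        raise ConfigError("n_genotypes_year1 cannot exceed n_genotypes")
    rng = np.random.default_rng(seed)
    gen = [f"G{i + 1:02d}" for i in range(n_genotypes)]
    locs = [f"L{i + 1:02d}" for i in range(n_locations)]
    years = [2021 + i for i in range(n_years)]
    g = rng.normal(0, np.sqrt(sigma2_g), n_genotypes)
    year_eff = rng.normal(0, 300.0, n_years)
    env_eff = rng.normal(0, 500.0, (n_locations, n_years))
    if kernel is None:
        ge = rng.normal(0, np.sqrt(sigma2_ge), (n_genotypes, n_locations))
    else:
        K = kernel.loc[locs, locs].to_numpy(dtype=float)
        w, V = np.linalg.eigh(K)
        L = V @ np.diag(np.sqrt(np.maximum(w, 0.0)))
        ge = np.sqrt(sigma2_ge) * rng.standard_normal((n_genotypes, n_locations)) @ L.T
    rows = []
    for yi, year in enumerate(years):
        gset = range(n_genotypes_year1) if (yi == 0 and n_years > 1) else range(n_genotypes)
        for li, loc in enumerate(locs):
            for gi in gset:
                y = (
                    mu
                    + year_eff[yi]
                    + env_eff[li, yi]
                    + g[gi]
                    + ge[gi, li]
                    + rng.normal(0, np.sqrt(sigma2_e))
                )
                rows.append((gen[gi], loc, year, y))
    blues = pd.DataFrame(rows, columns=["genotype", "location", "year", "blue"])
    blues["se"] = float(np.sqrt(sigma2_e))
    truth = {
        "genotype": sigma2_g,
        "genotype:location": sigma2_ge,
        "residual": sigma2_e,
        "genotype_effects": pd.Series(g, index=gen),
        "ge": pd.DataFrame(ge, index=gen, columns=locs),
    }
    return blues, truth
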