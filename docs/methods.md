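# Methods

This note documents the statistical models, the synthetic data-generating
process, the numerical choices, and the known limitations of the package.

## Mixed models and REML

All analyses use linear mixed models of the form

    y = X b + Σ_k Z_k u_k + e,   u_k ~ N(0, σ²_k K_k),   e ~ N(0, σ²_e I)

fitted by restricted maximum likelihood. The engine is dense (trial-network
data run to a few thousand plots, so no sparse machinery is needed) and
maximizes the REML log-likelihood

    ℓ_R = −½ [ (n−p) log 2π + log|V| + log|X′V⁻¹X| + y′Py ]

by average-information (AI) updates with several safeguards:

- the response is internally rescaled to unit variance so tolerances are
  scale-free; components are reported back on the data scale;
- the AI system is solved on the free components only — a component at the
  lower bound with a negative score is pinned at the boundary (KKT);
- updates are capped at unit length in scaled-variance units (trust region)
  and step-halved until the likelihood does not decrease; if no AI step
  helps, a multiplicative fixed-point update `σ² ← σ²·√(y′PGPy / tr(PG))`
  is tried;
- convergence: scaled score norm < 1e-8·n, or relative likelihood change
  < 1e-10; a numerical plateau with score < 1e-4·n at the boundary also
  counts as converged. Unconverged fits are flagged and raise a warning.
- variance components are floored at 1e-8 of var(y); floored components are
  reported as zero.

Fixed-effect design matrices are built from full dummy blocks in the order
declared; aliased columns are removed by greedy left-to-right rank
selection (reference-level drop), so environment-in-year fixed effects
absorb the year main effect without user intervention. BLUEs and their
covariance come from generalized least squares at the REML optimum; BLUPs
`û = σ²K Z′Py` carry full prediction-error-variance (PEV) matrices
`σ²K − σ⁴ K Z′PZK`.

**Two-stage analysis.** Stage 1 fits each trial separately: genotype as
fixed cell means; replicate, row and column as i.i.d. random effects. Row
and column random effects stand in for an explicit 2-D spatial smoother;
they capture the first-order field trend and keep the engine
self-contained, at the cost of not modeling smooth within-row gradients.
Stage 2 models the trial-level BLUEs with year and environment-in-year
fixed and genotype random; the second stage is unweighted by default — the
stage-1 standard errors are reported but not carried as weights (a
`fixed_components` escape hatch allows fitting at externally chosen
variance values).

**GxE covariance.** The genotype-by-environment term has observation-level
covariance `[Z_g Z_g′] ⊙ [Z_e K Z_e′]` with K the identity (MET, WC_MET,
OPT_MET), the enviromic kernel Ω (MET_EC), or a genotype-by-cluster
structure (cluster adjusted means). The environment factor for GxE is the
*location*, constant across years, so that the 18×18 kernel applies
directly; the trial (location × year) enters as a fixed effect.

**Cullis heritability.** `H² = 1 − v̄_Δ/(2σ̂²_g)` with v̄_Δ the mean variance
of a difference between genotype BLUPs, computed from the full PEV matrix
(`v̄_Δ = 2(q·tr C − ΣC)/(q(q−1))`). An alternative reading that substitutes
the mean PEV for v̄_Δ is available via `cullis_h2(..., vbar="mean_pev")`;
the pairwise-difference definition is the default. H² is clipped to [0, 1]
with clipping logged; σ̂²_g = 0 yields H² = 0 with a warning.

## Environmental covariates

Six phenological windows partition the season (days after emergence,
inclusive): 0–44, 45–59, 60–74, 75–89, 90–104, 105–148. Each daily weather
variable is averaged per window; two derived covariates are added per
window: the daily temperature range (max − min, window-averaged) and
growing degree-days, the window *sum* of
`max(0, (clip(t_min)+clip(t_max))/2 − t_base)` with both temperatures
clipped to `[t_base, t_max]`. Cardinal temperatures default to
t_base = 10 °C, t_opt = 30 °C, t_max = 42 °C — standard rice cardinal
values, configurable; t_opt is carried for completeness but does not enter
the capped-average GDD rule. With 17 simulated daily variables plus the two
derived ones, each environment gets 19 × 6 = 114 weather covariates; 11
soil covariates bring the joined matrix to 125 columns.

Columns are centered and scaled (sd with n−1); zero-variance columns are
dropped and logged, and environments lacking soil data are dropped from the
join with a warning. Collinearity QC then greedily removes, among columns
involved in any pair with |r| ≥ 0.95, the column with the largest mean
absolute correlation to all remaining columns (ties drop the later column),
until no offending pair remains; the result is audited against an
all-pairs check on every run.

## Covariate selection (RFE)

Repeated K-fold cross-validation (5 folds × 5 repeats) over environments
wraps a random-forest regressor (500 trees by default, sklearn defaults
otherwise). Within each training fold the forest is refit while features
are eliminated stepwise down the size grid {2, 4, 6, 8, 10, 12, 16, 24, 32,
all}∩[2, p], ranking by impurity importance at each step. Held-out
predictions are pooled within each repeat and scored as R² (pooling rather
than per-fold scoring, because folds of 3–4 environments make per-fold R²
essentially noise); the mean over repeats per size is the CV trace. The
size with the best mean CV R² (ties → smaller) is refit on all
environments; both the CV R² (headline) and the training R² of the final
model are reported. The response is the per-environment mean of stage-1
genotype BLUEs, so the headline reads as the share of yield variation
across sites explained by the selected covariates.

## Kernels

`Ω = W W′/(tr(W W′)/n)` guarantees symmetry, positive semidefiniteness and
trace = n, and is invariant to rescaling W. `Ω_yield` applies the same
normalization to the environment × genotype matrix of stage-1 BLUEs with
genotype columns centered/scaled over environments; untested
genotype × environment cells are imputed with the genotype's mean BLUE
(logged) — a pragmatic choice flagged in the output metadata, since the
yield-based matrix has no canonical construction. Kernels are compared by
the Pearson correlation of strict upper-triangle entries (diagonals are
normalization artifacts) and by Gaussian KDE summaries (Silverman
bandwidth, 512-point grid over the data range ± 3 bandwidths).

## Clustering, k choice, and TPE economics

K-means (k-means++ seeding, best of 50 starts, ≤300 Lloyd iterations,
seeded) clusters environments on the scaled selected covariates. The
number of clusters is chosen from the within-cluster-sum-of-squares trace
by an elbow rule: the smallest k whose WSS drop to k+1 falls below 10% of
the k=1→2 drop (threshold configurable; the full trace is always
reported). On structureless data the rule has no elbow and returns k_max —
the trace itself is the reliable diagnostic there. Cluster adjusted yield
means come from a model with cluster fixed (cell means), genotype random
and genotype × cluster random. New sites are assigned to the nearest
centroid in Euclidean distance on the same scaled space (ties → lowest
cluster index, logged). A two-pass TPE recipe (`two_step_tpe`) drops a
cluster that is both small (≤15% of sites) and far away (nearest centroid
beyond 2× the median inter-centroid distance, or 2× the RMS data spread
when only two clusters exist) and re-clusters the remainder — the pattern
produced by an environmentally isolated minority region. Economic
importance is the summed county production share per cluster (percent);
the allocation report pairs it with each cluster's share of historical
trials.

## Scenario economics

Costs use exact decimal arithmetic: genotypes × replicates × price/plot ×
locations × years, at $25/plot and $6/genotyped line by default. WC_MET
aggregates per-cluster H² as an unweighted mean ± SD, excluding (with a
warning) clusters with fewer than two environments. OPT_MET samples one
location per cluster uniformly without replacement, 10 replicates by
default, fully seeded. The advanced-trial location reduction is reported in
both readings — `100·(1 − k/n)` and the retained share `100·k/n` — because
the retained share is what a k-of-n subset conventionally gets quoted as in
cost summaries. The whole-network reduction simulation draws one location
per cluster, sums their historical trial counts, and averages
`100·(1 − retained/total)` over iterations; an exact enumeration mode
covers all draws for small problems. Percentages are rounded half-up to one
decimal.

## The synthetic trial network

The generator is the package's study system; its defaults are fixed
conditions, not tuning knobs.

- **Design**: 25 genotypes (9 tested in year 1, all 25 in year 2, the 9
  common), 18 locations, 2 years, RCBD with 3 blocks on a 15 × 5
  serpentine-filled grid; an optional 19th location carries weather but no
  soil record to exercise the join reduction.
- **Archetypes**: 5 climate/soil archetypes over the 18 locations (sizes
  4, 4, 4, 3, 3). Eight informative axes mirror the covariate classes that
  drive rice yield: dew-point temperature in three reproductive windows,
  minimum temperature and temperature range in the tillering–panicle
  window, thermal time pre-flowering, soil carbonate (TCEQ) and silt.
  Archetype offsets follow a shared climate gradient (levels 1, 0.5, 0,
  −0.5, −1 per archetype) plus Hadamard-sign axis deviations of 0.5 units,
  scaled per axis (≈4 °C for temperatures, 12 g/kg TCEQ, 8 g/100g silt).
  The gradient makes every informative axis marginally predictive of site
  yield (so an importance-based learner can find them), while the
  deviations keep axes from being collinear and give k-means multi-axis
  separation; within-cluster site jitter is 1 SD-unit per axis, and daily
  weather noise averages out over the ≥15-day windows. Under these
  conditions k-means on the true window means recovers the planted
  partition exactly.
- **Yield model** (kg/ha): μ = 8800; genotype σ²_g = 250,000; GxE
  σ²_ge = 60,000 with half its variance a linear reaction norm (genotype
  slopes × standardized informative covariates) and half i.i.d.; block
  40,000; row/column 22,500 each; plot residual 180,000. The location main
  effect is covariate-driven (300 kg/ha per SD of each informative axis)
  plus 150 kg/ha unexplained noise. These values reproduce the heritability
  regime of an elite advanced-trial network — Cullis H² ≈ 0.96–0.98 for the
  full MET with a moderate drop (≈0.05–0.07) under one-location-per-cluster
  optimization — which is the regime the optimization question is
  interesting in.
- **Counties**: 71 counties drawn from the same archetypes with Dirichlet
  (α = 0.35) production shares (strongly skewed, summing to 1 within
  1e-12); their full covariate profiles are generated through the same
  weather/soil machinery, so TPE clustering and site assignment operate on
  exactly the covariate space the locations use. Historical 10-year trial
  counts per location are skewed Dirichlet draws totalling ≈829.
- **Determinism**: a single seed drives a spawned seed tree; identical
  configurations are byte-identical, and changing the seed changes the
  noise but not the design skeleton.

**What the generator does not emulate**: real spatial field trends beyond
row/column effects, weather autocorrelation and seasonality (base profiles
are flat; only window contrasts matter downstream), genotype–year
interaction, non-Gaussian yield errors, and any geographic structure beyond
opaque location ids. Passing tests therefore demonstrate that the pipeline
recovers the structure it assumes — not that real networks satisfy those
assumptions.

## Problem sizes and checks

The test suite validates the engine against independent oracles: balanced
one-way ANOVA closed forms, a 50 × 50 grid search of the REML criterion on
≤30-observation instances (tolerance 1e-6 in log-likelihood), dense GLS and
PEV algebra for unbalanced designs, exhaustive enumeration for the
reduction simulation, and brute-force correlation audits for the
collinearity filter. Simulation-based checks use 20 seeded replicates at
the default design for variance-component recovery and for the
MET-vs-OPT_MET heritability comparison, 10 seeded runs at 60 environments
for RFE recovery of 3 planted covariates among 30 (at 18 environments
random-forest importance rankings are too unstable for recovery to be a
property of the method — a fact worth knowing when interpreting selections
on small networks), and 100–200 trees per forest in tests where the full
500-tree default adds stability the check does not need. RFE recovery
checks use a compact size grid including the planted size; the pipeline
default grid is unchanged.

## Known limitations

- The stage-1 model has no smooth spatial surface; strongly trending fields
  will leak trend into the residual and deflate stage-2 precision.
- The unweighted second stage treats all BLUEs as equally precise;
  severely unbalanced trials would warrant the weighted option.
- The elbow rule is a heuristic; for equivocal traces the reported WSS
  curve, not the chosen k, is the result.
- `Ω_yield` depends on the genotype × environment fill pattern; with many
  imputed cells its off-diagonals shrink toward the genotype-mean profile.
- REML variance components at the boundary (zero) make the corresponding
  BLUPs degenerate; the engine reports them as exactly zero rather than
  propagating floor-level noise.
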