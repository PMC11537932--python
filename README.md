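# enviromet

Optimization of multi-environment trial (MET) networks for plant breeding,
built around envirotyping: stage-windowed climate and soil covariates,
supervised covariate selection, enviromic relationship kernels,
mixed-model heritability per dollar, and economically weighted allocation of
trials to the target population of environments (TPE).

The package is aimed at quantitative geneticists and breeding-program
analysts asking: *how many testing locations does a trial network actually
need, which mega-environments do they represent, and what does each unit of
heritability cost?* It ships a fully synthetic rice trial-network generator
with known ground truth, so every stage of the pipeline can be validated
end to end on data whose answers are known.

## The method

1. **Stage-1 analysis.** Each trial (location × year, an RCBD with ≥3
   blocks) is analyzed with a linear mixed model
   `y = μ + G_i + R_j + L_m + C_n + ε` (genotype fixed; replicate, row and
   column i.i.d. random), yielding genotype BLUEs per trial.
2. **Envirotyping.** Daily weather per site is summarized over six rice
   phenological windows (emergence → maturity, days 0–148), including
   growing degree-days capped at rice cardinal temperatures, joined with
   soil covariates, standardized, and pruned of collinear columns
   (|r| ≥ 0.95), giving the environment × covariate matrix **W**.
3. **Covariate selection.** Recursive feature elimination with a random
   forest under 5-fold × 5-repeat cross-validation selects the covariates
   most predictive of site-mean yield.
4. **Enviromic kernel.** `Ω = W W′ / (tr(W W′)/n)` — a trace-normalized
   environment relationship matrix; `Ω_yield` is the analogous kernel from
   the environment × genotype BLUE matrix.
5. **Scenarios.** Stage-2 BLUP models
   `ȳ = μ + Y_x + G_i + E_j + GE_ij + ε` with GxE covariance
   `[Z_g Z_g′] ⊙ [Z_e Z_e′]` (MET), `[Z_g Z_g′] ⊙ Ω` (MET_EC), fitted per
   k-means mega-environment cluster (WC_MET), or on one sampled location per
   cluster (OPT_MET). Accuracy is Cullis broad-sense heritability
   `H² = 1 − v̄_Δ / (2 σ̂²_g)` with `v̄_Δ` the mean variance of a difference
   between genotype BLUPs, and each scenario is costed
   (genotypes × reps × $/plot × locations × years) to give H² per dollar.
6. **TPE allocation.** Counties are clustered on the selected covariates;
   cluster production shares (economic importance) are compared with the
   network's trial shares to flag mis-allocation.

All mixed models are fitted by a bespoke dense AI-REML engine
(`enviromet.lmm.MixedModelREML`, a scikit-learn-style estimator) that
supports supplied-kernel and Hadamard GxE covariance structures and returns
BLUEs, BLUPs and full prediction-error-variance matrices.

## Worked example

```python
from decimal import Decimal
from enviromet import (
    SimConfig, simulate_network, stage1_all_trials, kmeans_fit,
    run_met, run_opt_met, CostModel, trial_cost, reallocation_report,
)
from enviromet.covariates import build_W, filter_collinear, summarize_stage

net = simulate_network(SimConfig(seed=1))      # 25 genotypes, 18 sites, 2 years
blues = stage1_all_trials(net.plots)           # stage-1 genotype BLUEs per trial
W = filter_collinear(build_W(summarize_stage(net.weather), net.soil))
print(f"W matrix: {W.values.shape[0]} environments x {W.values.shape[1]} covariates")

informative = [c for c in net.truth.informative_covariates if c in W.values.columns]
clusters = kmeans_fit(W.values[informative], 5, seed=0)
cm_full = CostModel(25, 3, Decimal("25"), 18, 2)
cm_opt = CostModel(25, 3, Decimal("25"), 5, 2)
met = run_met(blues, cm_full)
opt = run_opt_met(blues, clusters.assignments, n_reps=10, seed=7, cost_model=cm_opt)
print(f"MET: H2 = {met.h2:.3f} at ${met.cost}")
print(f"OPT_MET: H2 = {opt.h2:.3f} +- {opt.h2_sd:.3f} at ${opt.cost}")
print(f"H2 per dollar: {opt.h2_per_dollar / met.h2_per_dollar:.1f}x the full network")
savings = trial_cost(cm_full) - trial_cost(cm_opt)
print(f"savings ${savings} ->", reallocation_report(savings, cm_full))
```

prints

```
W matrix: 18 environments x 113 covariates
MET: H2 = 0.981 at $67500
OPT_MET: H2 = 0.929 +- 0.010 at $18750
H2 per dollar: 3.4x the full network
savings $48750 -> {'additional_plots': 1950, 'additional_genotypes': 650, 'additional_genotyped_lines': 8125}
```

Reading: the full 18-location network reaches a Cullis heritability of
0.981 for $67,500 of phenotyping; keeping one location per mega-environment
drops H² only to 0.929 ± 0.010 while cutting the cost to $18,750 — about
3.4× the heritability per dollar. The $48,750 saved buys 1,950 extra plots
(650 genotypes at 3 reps) or genotyping for 8,125 lines at $6/line.

A command-line interface mirrors the library
(`enviromet simulate | blues | covariates | select | kernel | cluster |
scenarios | tpe | all`); `enviromet all --seed 1 --out artifacts` runs the
whole pipeline and writes every table plus a checksum manifest.

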