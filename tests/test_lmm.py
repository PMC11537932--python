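"""REML engine oracles: closed forms, grid search, dense GLS/MME algebra."""

import numpy as np
import pandas as pd
import pytest

from enviromet.exceptions import DataError
from enviromet.lmm import (
    HadamardTerm,
    MixedModelREML,
    ModelSpec,
    RandomFactor,
    cullis_h2,
    fit_reml,
    stage1_all_trials,
    stage1_blues,
    stage2_fit,
    variance_partition,
)
from enviromet.synthetic import SimConfig, simulate_met_blues, simulate_network

from conftest import small_config


def oracle_reml_loglik(y, X, G_list, sig):
    """Independent dense REML log-likelihood (textbook formula)."""
    n, p = X.shape
    V = sum(s * G for s, G in zip(sig, G_list))
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vinv = np.linalg.inv(V)
    C = X.T @ Vinv @ X
    signC, logdetC = np.linalg.slogdet(C)
    P = Vinv - Vinv @ X @ np.linalg.inv(C) @ X.T @ Vinv
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetC + y @ P @ y)


class TestRemlOracles:
    def test_balanced_one_way_closed_form(self):
        rng = np.random.default_rng(2)
        a, n = 8, 6
        u = rng.normal(0, 2.0, a)
        groups = np.repeat([f"g{i}" for i in range(a)], n)
        y = 5.0 + u[np.repeat(np.arange(a), n)] + rng.normal(0, 1.0, a * n)
        df = pd.DataFrame({"grp": groups, "y": y})
        fit = fit_reml(df, ModelSpec(response="y", random=(RandomFactor("grp"),)))
        gm = df.groupby("grp")["y"].mean()
        mse = ((df["y"] - df["grp"].map(gm)) ** 2).sum() / (a * (n - 1))
        msb = n * ((gm - y.mean()) ** 2).sum() / (a - 1)
        assert fit.varcomp_["residual"] == pytest.approx(mse, rel=1e-6)
        assert fit.varcomp_["grp"] == pytest.approx((msb - mse) / n, rel=1e-6)

    def test_grid_search_oracle_dominance(self):
        # tiny instance: 3 genotypes x 2 environments x 3 reps (18 obs)
        rng = np.random.default_rng(4)
        rows = []
        g_eff = {"A": -1.0, "B": 0.0, "C": 1.5}
        for g in "ABC":
            for e in ("E1", "E2"):
                for _ in range(3):
                    rows.append((g, e, 2.0 + g_eff[g] + rng.normal(0, 0.8)))
        df = pd.DataFrame(rows, columns=["genotype", "env", "y"])
        spec = ModelSpec(response="y", fixed=("env",), random=(RandomFactor("genotype"),))
        fit = MixedModelREML(spec).fit(df)

        # oracle design matrices built independently of the engine
        y = df["y"].to_numpy()
        X = np.column_stack([np.ones(len(df)), (df["env"] == "E2").to_numpy(float)])
        Zg = pd.get_dummies(df["genotype"]).to_numpy(float)
        Gs = [Zg @ Zg.T, np.eye(len(df))]
        best_grid = -np.inf
        for s_g in np.linspace(0.01, 4.0, 50):
            for s_e in np.linspace(0.01, 4.0, 50):
                best_grid = max(best_grid, oracle_reml_loglik(y, X, Gs, (s_g, s_e)))
        ll_hat = oracle_reml_loglik(
            y, X, Gs, (max(fit.varcomp_["genotype"], 1e-8), fit.varcomp_["residual"])
        )
        assert ll_hat >= best_grid - 1e-6

    def test_zero_noise_fixed_effects_exact(self):
        eff = {"A": 100.0, "B": 250.0, "C": -50.0}
        rows = [(g, r, eff[g]) for g in "ABC" for r in range(4)]
        df = pd.DataFrame(rows, columns=["genotype", "rep", "y"])
        spec = ModelSpec(response="y", cell_means="genotype", random=(RandomFactor("rep"),))
        fit = MixedModelREML(spec).fit(df)
        for g in "ABC":
            assert fit.beta_[f"genotype[{g}]"] == pytest.approx(eff[g], abs=1e-8)
        assert fit.varcomp_["rep"] == 0.0

    def test_fixed_components_skip_optimization(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"g": list("AABB") * 3, "y": rng.normal(size=12)})
        spec = ModelSpec(response="y", random=(RandomFactor("g"),))
        fit = MixedModelREML(spec, fixed_components={"g": 1.0, "residual": 2.0}).fit(df)
        assert fit.n_iter_ == 0 and fit.converged_


class TestStage1:
    def _rcbd(self, noise=0.0, block_sd=0.0, seed=0, drop_plot=False):
        rng = np.random.default_rng(seed)
        eff = {"G1": 0.0, "G2": 300.0, "G3": -200.0, "G4": 150.0}
        blocks = {b: rng.normal(0, block_sd) for b in (1, 2, 3)}
        rows = []
        i = 0
        for b in (1, 2, 3):
            for g in eff:
                rows.append((g, "L1", 2022, b, i // 4, i % 4,
                             8000 + eff[g] + blocks[b] + rng.normal(0, noise)))
                i += 1
        df = pd.DataFrame(rows, columns=["genotype", "location", "year",
                                         "replicate", "row", "column", "yield"])
        if drop_plot:
            df = df.iloc[1:]
        return df, eff

    def test_noise_free_blue_equals_genotype_mean(self):
        df, eff = self._rcbd()
        out = stage1_blues(df)
        for g, e in eff.items():
            assert out.loc[out.genotype == g, "blue"].iloc[0] == pytest.approx(8000 + e, abs=1e-6)

    def test_block_effects_orthogonal_to_genotypes(self):
        df, eff = self._rcbd(block_sd=250.0, seed=5)
        out = stage1_blues(df)
        gm = df.groupby("genotype")["yield"].mean()
        # tiny estimated row/column variances can perturb the equality at
        # floating precision; blocks themselves are orthogonal to genotypes
        for g in eff:
            assert out.loc[out.genotype == g, "blue"].iloc[0] == pytest.approx(gm[g], abs=1e-2)

    def test_unbalanced_matches_dense_gls_oracle(self):
        df, _ = self._rcbd(noise=150.0, block_sd=200.0, seed=9, drop_plot=True)
        out = stage1_blues(df)
        # dense GLS at the fitted variance components, built independently
        spec = ModelSpec(
            response="yield",
            cell_means="genotype",
            random=(RandomFactor("replicate"), RandomFactor("row"), RandomFactor("column")),
        )
        fit = MixedModelREML(spec).fit(df)
        X = pd.get_dummies(df["genotype"]).to_numpy(float)
        V = np.eye(len(df)) * max(fit.varcomp_raw_["residual"], 1e-10)
        for fac in ("replicate", "row", "column"):
            Z = pd.get_dummies(df[fac].astype(str)).to_numpy(float)
            V += max(fit.varcomp_raw_[fac], 1e-10) * Z @ Z.T
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ df["yield"].to_numpy())
        assert np.allclose(np.sort(out["blue"].to_numpy()), np.sort(beta), atol=1e-5)

    def test_preconditions(self):
        df, _ = self._rcbd()
        with pytest.raises(DataError):
            stage1_blues(df[df.replicate == 1])  # < 2 replicates
        two_trials = pd.concat([df, df.assign(location="L2")])
        with pytest.raises(DataError):
            stage1_blues(two_trials)


class TestStage2:
    def test_identity_kernel_degenerates_to_met(self, small_blues):
        locs = sorted(small_blues["location"].unique())
        identity = pd.DataFrame(np.eye(len(locs)), index=locs, columns=locs)
        met = stage2_fit(small_blues, variant="MET")
        ec = stage2_fit(small_blues, variant="MET_EC", kernel=identity)
        for k in met.varcomp_:
            assert ec.varcomp_[k] == pytest.approx(met.varcomp_[k], abs=1e-8 * (1 + met.varcomp_[k]))

    def test_single_environment_subset_rejected(self, small_blues):
        with pytest.raises(DataError):
            stage2_fit(small_blues, variant="WC", subset=["L01"])

    def test_kernel_environment_mismatch_rejected(self, small_blues):
        bad = pd.DataFrame(np.eye(2), index=["X", "Y"], columns=["X", "Y"])
        with pytest.raises(DataError):
            stage2_fit(small_blues, variant="MET_EC", kernel=bad)

    def test_noise_free_two_stage_recovers_genotype_ranking(self):
        cfg = small_config(
            seed=8,
            var_components={"genotype": 160_000.0, "gxe": 0.0, "block": 0.0,
                            "row": 0.0, "col": 0.0, "residual": 0.0},
            informative_covariates=(),
            loc_noise_sd=0.0,
        )
        net = simulate_network(cfg)
        blues = stage1_all_trials(net.plots)
        fit = stage2_fit(blues)
        blup = fit.blup_["genotype"]
        truth = net.truth.genotype_effects
        assert list(blup.sort_values().index) == list(truth.sort_values().index)


class TestCullisH2:
    class _Stub:
        def __init__(self, pev, s2g):
            q = pev.shape[0]
            idx = [f"G{i}" for i in range(q)]
            self.pev_ = {"genotype": pd.DataFrame(pev, index=idx, columns=idx)}
            self.varcomp_ = {"genotype": s2g}

    def test_boundary_identities(self):
        # constant PEV matrix: every pairwise difference has zero variance
        assert cullis_h2(self._Stub(np.full((5, 5), 0.3), 1.0)) == 1.0
        # PEV = s2g * I: vbar_delta = 2 s2g
        assert cullis_h2(self._Stub(np.eye(5) * 2.0, 2.0)) == 0.0

    def test_dense_mme_oracle_on_balanced_toy(self):
        rng = np.random.default_rng(3)
        gen = [f"G{i}" for i in range(6)]
        envs = [f"E{j}" for j in range(4)]
        rows = [(g, e, 2022, rng.normal()) for g in gen for e in envs]
        df = pd.DataFrame(rows, columns=["genotype", "location", "year", "blue"])
        comp = {"genotype": 1.0, "genotype:location": 0.5, "residual": 0.7}
        fit = stage2_fit(df, fixed_components=comp)
        # oracle: PEV from the dense variance algebra at the same components
        Zg = pd.get_dummies(df["genotype"]).to_numpy(float)
        Ze = pd.get_dummies(df["location"]).to_numpy(float)
        n = len(df)
        V = comp["genotype"] * Zg @ Zg.T + comp["genotype:location"] * (
            (Zg @ Zg.T) * (Ze @ Ze.T)
        ) + comp["residual"] * np.eye(n)
        X = np.column_stack([np.ones(n), pd.get_dummies(df["location"]).to_numpy(float)[:, 1:]])
        Vinv = np.linalg.inv(V)
        P = Vinv - Vinv @ X @ np.linalg.inv(X.T @ Vinv @ X) @ X.T @ Vinv
        K = np.eye(len(gen))
        pev = comp["genotype"] * K - comp["genotype"] ** 2 * (Zg.T @ P @ Zg)
        q = len(gen)
        vbar = 2 * (q * np.trace(pev) - pev.sum()) / (q * (q - 1))
        expected = 1 - vbar / (2 * comp["genotype"])
        assert cullis_h2(fit) == pytest.approx(expected, abs=1e-8)

    def test_h2_degrades_with_inflated_residual(self, small_blues):
        base = stage2_fit(
            small_blues,
            fixed_components={"genotype": 2e5, "genotype:location": 6e4, "residual": 6e4},
        )
        noisy = stage2_fit(
            small_blues,
            fixed_components={"genotype": 2e5, "genotype:location": 6e4, "residual": 6e5},
        )
        assert cullis_h2(noisy) < cullis_h2(base)

    def test_zero_genotypic_variance_warns(self, small_blues):
        fit = stage2_fit(
            small_blues,
            fixed_components={"genotype": 1e-12, "genotype:location": 6e4, "residual": 6e4},
        )
        fit.varcomp_["genotype"] = 0.0
        with pytest.warns(RuntimeWarning):
            assert cullis_h2(fit) == 0.0

    def test_mean_pev_variant_differs(self, small_blues):
        fit = stage2_fit(small_blues)
        a = cullis_h2(fit, vbar="pair_difference")
        b = cullis_h2(fit, vbar="mean_pev")
        assert 0.0 <= b <= 1.0 and a != b


class TestBlupBehaviour:
    def test_blup_shrinkage_monotone_in_residual_variance(self):
        df = pd.DataFrame(
            {"g": ["A"] * 4 + ["B"] * 4, "y": [3.0, 2.5, 3.5, 3.0, -3.0, -2.5, -3.5, -3.0]}
        )
        spec = ModelSpec(response="y", random=(RandomFactor("g"),))
        norms = []
        for s2e in (0.5, 5.0, 50.0, 500.0):
            fit = MixedModelREML(spec, fixed_components={"g": 4.0, "residual": s2e}).fit(df)
            norms.append(np.abs(fit.blup_["g"]).max())
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 0.2  # BLUPs shrink toward zero


class TestVariancePartition:
    def test_proportions_sum_to_one(self, small_blues):
        vp = variance_partition(small_blues)
        assert vp["proportion"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_dominant_gxe_recovered(self):
        blues, _ = simulate_met_blues(
            n_genotypes=15, n_genotypes_year1=15, n_locations=10, n_years=2,
            sigma2_g=20_000.0, sigma2_ge=400_000.0, sigma2_e=20_000.0, seed=5,
        )
        vp = variance_partition(blues)
        non_resid = vp.drop(index=["residual"])["variance"]
        assert non_resid.idxmax() == "genotype:location"

    def test_absent_component_estimated_near_zero(self):
        blues, truth = simulate_met_blues(
            n_genotypes=15, n_genotypes_year1=15, n_locations=10, n_years=2,
            sigma2_g=0.0, sigma2_ge=50_000.0, sigma2_e=50_000.0, seed=6,
        )
        vp = variance_partition(blues)
        assert vp.loc["genotype", "proportion"] < 0.05
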