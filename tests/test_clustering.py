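"""Mega-environment clustering, TPE economics, PCA and site assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from enviromet.clustering import (
    MegaEnvironmentKMeans,
    assign_sites,
    choose_k,
    cluster_adjusted_means,
    economic_importance,
    kmeans_fit,
    pca_summary,
    trial_allocation,
    two_step_tpe,
    wss_trace,
)
from enviromet.exceptions import ConfigError, DataError


def _blobs(centers, per=4, sd=0.3, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for c, center in enumerate(centers):
        for _ in range(per):
            rows.append(center + rng.normal(0, sd, len(center)))
            labels.append(c)
    X = pd.DataFrame(rows, index=[f"E{i:02d}" for i in range(len(rows))])
    return X, pd.Series(labels, index=X.index)


class TestKMeans:
    def test_two_planted_archetypes_recovered(self):
        X, truth = _blobs([np.zeros(3), np.full(3, 5.0)], per=6)
        model = kmeans_fit(X, 2, seed=0)
        assert adjusted_rand_score(truth, model.assignments) == 1.0

    def test_k_equals_n_gives_zero_wss(self):
        X, _ = _blobs([np.zeros(2), np.ones(2) * 4], per=3)
        assert kmeans_fit(X, len(X), seed=0).wss == pytest.approx(0.0, abs=1e-12)

    def test_identical_rows_single_cluster(self):
        X = pd.DataFrame(np.tile([1.0, 2.0], (5, 1)), index=[f"E{i}" for i in range(5)])
        model = kmeans_fit(X, 1, seed=0)
        assert model.wss == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(model.centroids.iloc[0], [1.0, 2.0])

    @pytest.mark.parametrize("k", [0, 99])
    def test_invalid_k_rejected(self, k):
        X, _ = _blobs([np.zeros(2)], per=4)
        with pytest.raises(ConfigError):
            kmeans_fit(X, k, seed=0)

    def test_deterministic_given_seed(self):
        X, _ = _blobs([np.zeros(3), np.ones(3) * 3, np.ones(3) * -3], per=5, sd=0.8)
        a = kmeans_fit(X, 3, seed=5)
        b = kmeans_fit(X, 3, seed=5)
        pd.testing.assert_series_equal(a.assignments, b.assignments)

    def test_wss_trace_non_increasing(self, default_W):
        trace = wss_trace(default_W.values, 8, seed=0)
        assert (np.diff(trace.to_numpy()) <= 1e-9).all()


class TestChooseK:
    def test_separable_five_clusters(self, default_net):
        twm = default_net.truth.true_window_means
        std = (twm - twm.mean()) / twm.std(ddof=1)
        trace = wss_trace(std, 8, seed=0)
        assert choose_k(trace) == 5

    def test_single_blob_trace_monotone(self):
        # a structureless blob has no elbow; the contract is a monotone trace
        X, _ = _blobs([np.zeros(4)], per=12, sd=1.0)
        trace = wss_trace(X, 6, seed=0)
        assert (np.diff(trace.to_numpy()) <= 1e-9).all()
        assert 1 <= choose_k(trace) <= len(trace)

    def test_k_max_one(self):
        trace = pd.Series({1: 10.0})
        assert choose_k(trace, k_max=1) == 1


class TestAdjustedMeans:
    def _cluster_blues(self, offsets, per_cluster=3, n_gen=6, noise=0.0, seed=0,
                       unbalanced=False):
        rng = np.random.default_rng(seed)
        g_eff = rng.normal(0, 1.0, n_gen)
        g_eff -= g_eff.mean()  # the random-effect mean is absorbed by the fixed means
        rows = []
        assign = {}
        li = 0
        for c, off in enumerate(offsets, start=1):
            for _ in range(per_cluster):
                loc = f"L{li:02d}"
                assign[loc] = c
                li += 1
                for g in range(n_gen):
                    rows.append((loc, 2022, f"G{g}", 100.0 + off + g_eff[g]
                                 + rng.normal(0, noise)))
        df = pd.DataFrame(rows, columns=["location", "year", "genotype", "blue"])
        if unbalanced:
            df = df.iloc[2:]
        return df, pd.Series(assign), np.array(offsets)

    def test_noise_free_planted_offsets_recovered(self):
        blues, assign, offsets = self._cluster_blues([0.0, 50.0, -30.0])
        means = cluster_adjusted_means(blues, assign)
        assert np.allclose(means.to_numpy(), 100.0 + offsets, atol=1e-6)

    def test_balanced_equals_raw_cluster_means(self):
        blues, assign, _ = self._cluster_blues([0.0, 40.0], noise=5.0, seed=2)
        means = cluster_adjusted_means(blues, assign)
        raw = blues.assign(cluster=blues["location"].map(assign)).groupby("cluster")["blue"].mean()
        assert np.allclose(means.to_numpy(), raw.to_numpy(), atol=1e-6)

    def test_unbalanced_matches_dense_gls_oracle(self):
        blues, assign, _ = self._cluster_blues([0.0, 40.0], noise=8.0, seed=3,
                                               unbalanced=True)
        means = cluster_adjusted_means(blues, assign)
        # oracle GLS at the fitted components
        from enviromet.lmm import HadamardTerm, MixedModelREML, ModelSpec, RandomFactor

        df = blues.assign(cluster=blues["location"].map(assign).astype(str))
        spec = ModelSpec(response="blue", cell_means="cluster",
                         random=(RandomFactor("genotype"), HadamardTerm("genotype", "cluster")))
        fit = MixedModelREML(spec).fit(df)
        Zg = pd.get_dummies(df["genotype"]).to_numpy(float)
        Zc = pd.get_dummies(df["cluster"]).to_numpy(float)
        n = len(df)
        V = (max(fit.varcomp_raw_["genotype"], 1e-12) * Zg @ Zg.T
             + max(fit.varcomp_raw_["genotype:cluster"], 1e-12) * ((Zg @ Zg.T) * (Zc @ Zc.T))
             + max(fit.varcomp_raw_["residual"], 1e-12) * np.eye(n))
        Vinv = np.linalg.inv(V)
        X = Zc
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ df["blue"].to_numpy())
        assert np.allclose(np.sort(means.to_numpy()), np.sort(beta), atol=1e-6)

    def test_unassigned_environment_rejected(self):
        blues, assign, _ = self._cluster_blues([0.0, 40.0])
        with pytest.raises(DataError):
            cluster_adjusted_means(blues, assign.iloc[:-1])


class TestAssignSites:
    def test_profile_equal_to_centroid(self):
        centroids = pd.DataFrame([[0.0, 0.0], [5.0, 5.0]], index=[1, 2], columns=["a", "b"])
        prof = pd.DataFrame([[5.0, 5.0]], index=["X"], columns=["a", "b"])
        assert assign_sites(prof, centroids)["X"] == 2

    def test_equidistant_goes_to_lowest_index(self, caplog):
        centroids = pd.DataFrame([[-1.0], [1.0]], index=[1, 2], columns=["a"])
        prof = pd.DataFrame([[0.0]], index=["X"], columns=["a"])
        with caplog.at_level("INFO", logger="enviromet.clustering"):
            out = assign_sites(prof, centroids)
        assert out["X"] == 1
        assert any("equidistant" in r.message for r in caplog.records)

    def test_matches_exhaustive_distance_scan(self):
        rng = np.random.default_rng(8)
        centroids = pd.DataFrame(rng.normal(size=(4, 3)), index=[1, 2, 3, 4],
                                 columns=["a", "b", "c"])
        prof = pd.DataFrame(rng.normal(size=(20, 3)), index=[f"S{i}" for i in range(20)],
                            columns=["a", "b", "c"])
        out = assign_sites(prof, centroids)
        D = cdist(prof.to_numpy(), centroids.to_numpy())
        expected = centroids.index[np.argmin(D, axis=1)]
        assert (out.to_numpy() == np.asarray(expected)).all()

    def test_training_environments_reproduce_kmeans_assignments(self, default_W):
        model = kmeans_fit(default_W.values, 5, seed=0)
        again = assign_sites(default_W.values, model.centroids)
        assert (again == model.assignments).all()


class TestPca:
    def test_rank_one_matrix(self):
        u = np.arange(1, 6, dtype=float)
        W = pd.DataFrame(np.outer(u - u.mean(), [1.0, 2.0, -1.0]))
        p = pca_summary(W)
        assert p.variance_fraction["PC1"] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_reconstruction(self, default_W):
        p = pca_summary(default_W.values)
        A = default_W.values.to_numpy()
        A = A - A.mean(axis=0)
        recon = p.scores.to_numpy() @ p.loadings.to_numpy().T
        assert np.allclose(recon, A, atol=1e-8)

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(0)
        W = pd.DataFrame(rng.normal(size=(200, 4)))
        p = pca_summary(W)
        assert p.variance_fraction.max() < 0.4
        assert p.variance_fraction.sum() == pytest.approx(1.0)


class TestEconomics:
    def test_worked_example(self):
        production = pd.DataFrame(
            {"county": ["A", "B", "C"], "production_share": [0.5, 0.3, 0.2]}
        )
        assign = pd.Series({"A": 1, "B": 1, "C": 2})
        out = economic_importance(production, assign)
        assert out[1] == pytest.approx(80.0)
        assert out[2] == pytest.approx(20.0)

    def test_single_cluster_is_100(self):
        production = pd.DataFrame({"county": ["A", "B"], "production_share": [0.6, 0.4]})
        out = economic_importance(production, pd.Series({"A": 1, "B": 1}))
        assert out[1] == pytest.approx(100.0)

    def test_random_table_matches_hand_summation(self):
        rng = np.random.default_rng(5)
        shares = rng.dirichlet(np.ones(12))
        counties = [f"C{i}" for i in range(12)]
        clusters = pd.Series(rng.integers(1, 4, 12), index=counties)
        production = pd.DataFrame({"county": counties, "production_share": shares})
        out = economic_importance(production, clusters)
        for c in out.index:
            hand = shares[clusters.to_numpy() == c].sum() * 100
            assert out[c] == pytest.approx(hand)
        assert out.sum() == pytest.approx(100.0, abs=1e-9)

    def test_trial_allocation_partition_shares(self):
        # 18 locations, 1 trial each, clusters of sizes 7/9/1/1
        locs = [f"L{i:02d}" for i in range(18)]
        sizes = [7, 9, 1, 1]
        assign = {}
        i = 0
        for c, s in enumerate(sizes, start=1):
            for _ in range(s):
                assign[locs[i]] = c
                i += 1
        counts = pd.Series(1, index=locs)
        out = trial_allocation(counts, pd.Series(assign))
        assert out[1] == pytest.approx(100 * 7 / 18)
        assert out[2] == pytest.approx(100 * 9 / 18)
        assert out[3] == pytest.approx(100 * 1 / 18)
        assert [round(v, 1) for v in out] == [38.9, 50.0, 5.6, 5.6]
        assert out.sum() == pytest.approx(100.0, abs=1e-9)

    def test_weighted_counts_hand_sum(self):
        counts = pd.Series({"L1": 10, "L2": 30, "L3": 60})
        assign = pd.Series({"L1": 1, "L2": 1, "L3": 2})
        out = trial_allocation(counts, assign)
        assert out[1] == pytest.approx(40.0)
        assert out[2] == pytest.approx(60.0)


class TestTwoStepTpe:
    def test_outlier_cluster_dropped_and_reclustered(self):
        # 3 tight groups plus a tiny far-away group (the outlier region)
        X, _ = _blobs([np.zeros(4), np.full(4, 6.0), np.array([6.0, 0, 6.0, 0])],
                      per=8, sd=0.4, seed=1)
        far, _ = _blobs([np.full(4, 60.0)], per=2, sd=0.4, seed=2)
        far.index = ["F0", "F1"]
        allX = pd.concat([X, far])
        out = two_step_tpe(allX, k_max=6, seed=0, n_init=20)
        assert set(out["outliers"]) == {"F0", "F1"}
        assert out["k_final"] == 3

    def test_no_outliers_keeps_everything(self):
        X, _ = _blobs([np.zeros(3), np.full(3, 5.0)], per=6, sd=0.4, seed=3)
        out = two_step_tpe(X, k_max=5, seed=0, n_init=20)
        assert out["outliers"] == []
        assert len(out["final"].assignments) == len(X)


class TestEstimatorInterface:
    def test_mega_environment_kmeans_chooses_k(self, default_net):
        twm = default_net.truth.true_window_means
        std = (twm - twm.mean()) / twm.std(ddof=1)
        est = MegaEnvironmentKMeans(seed=0, n_init=20).fit(std)
        assert est.k_ == 5
        pred = est.predict(std)
        assert (pred == est.labels_).all()
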