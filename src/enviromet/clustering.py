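"""Mega-environment delimitation and TPE economics.

Locations (or counties) are clustered by k-means on the selected, scaled
environmental covariates; the number of clusters is chosen from the
within-cluster sum of squares (WSS) trace by an elbow rule. Cluster adjusted
yield means come from a mixed model with cluster fixed and genotype and
genotype-by-cluster random. New sites are assigned to the nearest centroid
in Euclidean distance on the scaled covariate space, and each cluster's
economic importance (county production share) is paired with its share of
trials for the allocation report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .exceptions import ConfigError, DataError
from .lmm import HadamardTerm, MixedModelREML, ModelSpec, RandomFactor

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterModel",
    "PcaSummary",
    "MegaEnvironmentKMeans",
    "kmeans_fit",
    "wss_trace",
    "choose_k",
    "cluster_adjusted_means",
    "assign_sites",
    "pca_summary",
    "economic_importance",
    "trial_allocation",
    "two_step_tpe",
]


def _as_frame(W) -> pd.DataFrame:
    values = getattr(W, "values", W)
    if isinstance(values, pd.DataFrame):
        df = values
    else:
        df = pd.DataFrame(W)
    df = df.copy()
    df.index = df.index.astype(str)
    return df


@dataclass
class ClusterModel:
    """Fitted k-means partition of environments on the scaled W space."""

    k: int
    assignments: pd.Series  # environment -> cluster id (1-based)
    centroids: pd.DataFrame  # k x covariates
    wss: float
    wss_trace: Optional[pd.Series]  # k -> WSS, when a trace was computed
    seed: int
    n_init: int


@dataclass
class PcaSummary:
    scores: pd.DataFrame  # environment x component
    loadings: pd.DataFrame  # covariate x component
    variance_fraction: pd.Series  # per component


# k-means itself is delegated to sklearn (Lloyd + k-means++, best of n_init);
# the surface here adds deterministic ids, the WSS trace and the elbow rule.


def kmeans_fit(W, k: int, seed: int = 0, n_init: int = 50) -> ClusterModel:
    """Best-of-n_init k-means with k-means++ seeding; deterministic per seed."""
    X = _as_frame(W)
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > len(X):
        raise ConfigError(f"k={k} exceeds the number of environments ({len(X)})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=300, random_state=seed)
    labels = km.fit_predict(X.to_numpy(dtype=float))
    return ClusterModel(
        k=k,
        assignments=pd.Series(labels + 1, index=X.index, name="cluster"),
        centroids=pd.DataFrame(km.cluster_centers_, index=range(1, k + 1), columns=X.columns),
        wss=float(km.inertia_),
        wss_trace=None,
        seed=seed,
        n_init=n_init,
    )


def wss_trace(W, k_max: int, seed: int = 0, n_init: int = 50) -> pd.Series:
    """Within-cluster sum of squares for k = 1..k_max."""
    X = _as_frame(W)
    k_max = min(k_max, len(X))
    vals = {k: kmeans_fit(X, k, seed=seed, n_init=n_init).wss for k in range(1, k_max + 1)}
    return pd.Series(vals, name="wss")


def choose_k(trace: pd.Series, k_max: Optional[int] = None, rel_drop: float = 0.10) -> int:
    """Elbow rule on a WSS trace.

    Returns the smallest k whose WSS drop to k+1 falls below ``rel_drop``
    times the k=1 -> 2 drop. Degenerate traces (no drop at all) give k=1.
    """
    t = trace.sort_index()
    if k_max is not None:
        t = t[t.index <= k_max]
    ks = list(t.index)
    if len(ks) <= 1:
        return int(ks[0]) if ks else 1
    drops = {k: t[k] - t[k + 1] for k in ks[:-1]}
    base = drops[ks[0]]
    if base <= 0:
        return 1
    for k in ks[:-1]:
        if drops[k] < rel_drop * base:
            return int(k)
    return int(ks[-1])


class MegaEnvironmentKMeans(BaseEstimator, ClusterMixin):
    """Sklearn-style mega-environment clusterer.

    With ``k=None`` the number of clusters is chosen from the WSS trace by
    the elbow rule (up to ``k_max``). Fitted attributes: ``labels_``,
    ``cluster_model_`` (a :class:`ClusterModel`), ``k_``, ``wss_trace_``.
    """

    def __init__(self, k: Optional[int] = None, k_max: int = 8, seed: int = 0,
                 n_init: int = 50, rel_drop: float = 0.10):
        self.k = k
        self.k_max = k_max
        self.seed = seed
        self.n_init = n_init
        self.rel_drop = rel_drop

    def fit(self, X, y=None):
        Xdf = _as_frame(X)
        trace = wss_trace(Xdf, self.k_max, seed=self.seed, n_init=self.n_init)
        k = self.k if self.k is not None else choose_k(trace, rel_drop=self.rel_drop)
        model = kmeans_fit(Xdf, k, seed=self.seed, n_init=self.n_init)
        model.wss_trace = trace
        self.cluster_model_ = model
        self.k_ = k
        self.wss_trace_ = trace
        self.labels_ = model.assignments.to_numpy()
        return self

    def predict(self, X):
        return assign_sites(X, self.cluster_model_.centroids).to_numpy()


def cluster_adjusted_means(
    blues: pd.DataFrame, assignments: pd.Series, **fit_kwargs
) -> pd.Series:
    """Per-cluster adjusted grain-yield means.

    Cluster is fixed (cell means), genotype random, genotype x cluster random
    with Hadamard structure; the fixed-effect estimates are the adjusted
    means on the response scale.
    """
    df = blues.copy()
    df["location"] = df["location"].astype(str)
    amap = assignments.copy()
    amap.index = amap.index.astype(str)
    missing = sorted(set(df["location"]) - set(amap.index))
    if missing:
        raise DataError(f"environments without cluster assignment: {missing[:5]}")
    df["cluster"] = df["location"].map(amap).astype(int).astype(str)
    counts = df.groupby("cluster").size()
    if (counts == 0).any():  # pragma: no cover - map construction prevents it
        raise DataError("a cluster has zero observations")
    spec = ModelSpec(
        response="blue",
        cell_means="cluster",
        random=(RandomFactor("genotype"), HadamardTerm("genotype", "cluster")),
    )
    fit = MixedModelREML(spec, **fit_kwargs).fit(df)
    means = {
        int(nm[len("cluster[") : -1]): float(v) for nm, v in fit.beta_.items()
    }
    return pd.Series(means).sort_index()


def assign_sites(profiles, centroids: pd.DataFrame) -> pd.Series:
    """Nearest-centroid assignment on the scaled covariate space.

    Ties go to the lowest cluster index (logged).
    """
    P = _as_frame(profiles)
    C = centroids[P.columns] if set(P.columns) <= set(centroids.columns) else None
    if C is None:
        raise DataError("profiles and centroids have different covariate columns")
    D = cdist(P.to_numpy(dtype=float), C.to_numpy(dtype=float))
    idx = np.argmin(D, axis=1)  # argmin takes the first (lowest) on ties
    ties = (D == D[np.arange(len(P)), idx][:, None]).sum(axis=1) > 1
    for site in P.index[ties]:
        logger.info("site %s equidistant to several centroids; lowest index chosen", site)
    clusters = np.asarray(C.index)[idx]
    return pd.Series(clusters, index=P.index, name="cluster")


def pca_summary(W) -> PcaSummary:
    """Principal components of the (already scaled) W matrix via SVD."""
    X = _as_frame(W)
    A = X.to_numpy(dtype=float)
    A = A - A.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    n_comp = len(s)
    comp = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(U * s, index=X.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comp)
    total = float(np.sum(s**2))
    frac = pd.Series((s**2) / total if total > 0 else np.zeros(n_comp), index=comp)
    return PcaSummary(scores=scores, loadings=loadings, variance_fraction=frac)


def economic_importance(production: pd.DataFrame, assignments: pd.Series) -> pd.Series:
    """Per-cluster production share in percent (sums to 100)."""
    for c in ("county", "production_share"):
        if c not in production.columns:
            raise DataError(f"production table missing column {c!r}")
    amap = assignments.copy()
    amap.index = amap.index.astype(str)
    df = production.copy()
    df["county"] = df["county"].astype(str)
    missing = sorted(set(df["county"]) - set(amap.index))
    if missing:
        raise DataError(f"counties without cluster assignment: {missing[:5]}")
    df["cluster"] = df["county"].map(amap)
    total = df["production_share"].sum()
    if total <= 0:
        raise DataError("production shares sum to zero")
    out = df.groupby("cluster")["production_share"].sum() / total * 100.0
    return out.sort_index()


def trial_allocation(trial_counts: pd.Series, assignments: pd.Series) -> pd.Series:
    """Per-cluster share of trials in percent (sums to 100)."""
    counts = pd.Series(trial_counts).copy()
    counts.index = counts.index.astype(str)
    amap = assignments.copy()
    amap.index = amap.index.astype(str)
    missing = sorted(set(counts.index) - set(amap.index))
    if missing:
        raise DataError(f"locations without cluster assignment: {missing[:5]}")
    total = counts.sum()
    if total <= 0:
        raise DataError("no trials to allocate")
    df = pd.DataFrame({"n": counts, "cluster": amap.loc[counts.index]})
    return (df.groupby("cluster")["n"].sum() / total * 100.0).sort_index()


def two_step_tpe(
    profiles,
    k_max: int = 8,
    seed: int = 0,
    n_init: int = 50,
    outlier_size_frac: float = 0.15,
    outlier_dist_factor: float = 2.0,
) -> dict:
    """Cluster, drop a small far-away outlier group, re-cluster.

    Mirrors a two-pass TPE delimitation in which a first clustering exposes
    an environmentally isolated minority group (dropped), and the remaining
    sites are re-clustered. Returns a dict with both ClusterModels, the
    outlier members, and the k chosen at each pass.
    """
    X = _as_frame(profiles)
    tr1 = wss_trace(X, k_max, seed=seed, n_init=n_init)
    k1 = choose_k(tr1)
    m1 = kmeans_fit(X, k1, seed=seed, n_init=n_init)
    m1.wss_trace = tr1
    dropped: list = []
    if k1 > 1:
        sizes = m1.assignments.value_counts()
        C = m1.centroids.to_numpy(dtype=float)
        D = cdist(C, C)
        if k1 >= 3:
            scale = float(np.median(D[np.triu_indices(k1, k=1)]))
        else:
            # with two clusters there is no inter-centroid distribution;
            # compare against the RMS spread of the data instead
            A = X.to_numpy(dtype=float)
            scale = float(np.sqrt(((A - A.mean(axis=0)) ** 2).sum(axis=1).mean()))
        for c in sizes.index:
            others = [i for i in range(k1) if i != c - 1]
            dmin = D[c - 1, others].min()
            if sizes[c] <= outlier_size_frac * len(X) and dmin > outlier_dist_factor * scale:
                dropped = list(m1.assignments.index[m1.assignments == c])
                logger.info("dropping outlier cluster %d (%d sites)", c, len(dropped))
                break
    X2 = X.drop(index=dropped)
    tr2 = wss_trace(X2, k_max, seed=seed, n_init=n_init)
    k2 = choose_k(tr2)
    m2 = kmeans_fit(X2, k2, seed=seed, n_init=n_init)
    m2.wss_trace = tr2
    return {"first_pass": m1, "outliers": dropped, "final": m2, "k_first": k1, "k_final": k2}
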