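"""Linear mixed models for multi-environment trial analysis.

The engine fits models of the form

    y = X b + sum_k Z_k u_k + e,    u_k ~ N(0, s2_k K_k),   e ~ N(0, s2_e I)

by restricted maximum likelihood (REML), using average-information (AI)
updates with a step-halving / fixed-point fallback, and returns variance
components, BLUEs of the fixed effects with standard errors, and BLUPs of the
random effects with full prediction-error-variance (PEV) matrices.

Random terms are either plain factors (identity or supplied kernel
covariance) or a single Hadamard genotype-by-environment term whose
observation-level covariance is [Z_g Z_g'] .* [Z_e K Z_e'] — the structure
used for GxE with an identity or enviromic kernel K.

Sizes here are those of breeding-trial data (hundreds to a few thousand
plots), so all algebra is dense.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .exceptions import ConvergenceError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "RandomFactor",
    "HadamardTerm",
    "ModelSpec",
    "MixedModelREML",
    "fit_reml",
    "stage1_blues",
    "stage1_all_trials",
    "stage2_fit",
    "cullis_h2",
    "variance_partition",
]


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomFactor:
    """A random factor with identity or supplied kernel covariance.

    ``kernel`` is a square DataFrame indexed by factor levels; ``None`` means
    identity (i.i.d. levels).
    """

    factor: str
    kernel: Optional[pd.DataFrame] = None

    @property
    def name(self) -> str:
        return self.factor


@dataclass(frozen=True)
class HadamardTerm:
    """GxE-style interaction: covariance [Z_a Z_a'] .* [Z_b K_b Z_b']."""

    factor_a: str
    factor_b: str
    kernel_b: Optional[pd.DataFrame] = None

    @property
    def name(self) -> str:
        return f"{self.factor_a}:{self.factor_b}"


RandomTerm = Union[RandomFactor, HadamardTerm]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    fixed       ordered factor names entering as full dummy blocks; aliased
                columns are dropped sequentially (reference-level drop).
    cell_means  if set, that factor is coded as cell means (no intercept), so
                its fixed-effect estimates are directly adjusted means.
    random      RandomFactor / HadamardTerm entries; at most one Hadamard.
    """

    response: str
    fixed: tuple = ()
    random: tuple = ()
    intercept: bool = True
    cell_means: Optional[str] = None

    def __post_init__(self):
        n_had = sum(isinstance(t, HadamardTerm) for t in self.random)
        if n_had > 1:
            raise DataError("at most one Hadamard (GxE) term is supported")


def _dummies(values: pd.Series) -> tuple[list, np.ndarray]:
    """Indicator matrix with deterministic (sorted) level order."""
    cats = pd.Categorical(values.astype(str))
    levels = sorted(cats.categories)
    cats = cats.reorder_categories(levels)
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), cats.codes] = 1.0
    return list(levels), Z


def _sequential_rank_keep(X: np.ndarray, tol: float = 1e-9) -> list[int]:
    """Indices of columns kept by greedy left-to-right rank selection."""
    n = X.shape[0]
    basis = np.zeros((n, 0))
    keep: list[int] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        nrm = np.linalg.norm(col)
        if nrm == 0:
            continue
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
        else:
            resid = col.copy()
        if np.linalg.norm(resid) > tol * nrm:
            keep.append(j)
            basis = np.hstack([basis, (resid / np.linalg.norm(resid))[:, None]])
    return keep


def _align_kernel(kernel: pd.DataFrame, levels: Sequence[str], what: str) -> np.ndarray:
    idx = [str(i) for i in kernel.index]
    missing = [l for l in levels if l not in idx]
    if missing:
        raise DataError(f"{what} kernel is missing levels: {missing[:5]}")
    K = kernel.copy()
    K.index = idx
    K.columns = [str(c) for c in kernel.columns]
    K = K.loc[list(levels), list(levels)].to_numpy(dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise DataError(f"{what} kernel is not symmetric")
    return K


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------


class MixedModelREML(BaseEstimator):
    """REML mixed-model estimator (sklearn-style).

    Parameters
    ----------
    spec : ModelSpec
    max_iter : int
        Maximum AI-REML iterations.
    grad_tol : float
        Convergence on the infinity norm of the REML score (scaled response).
    ll_tol : float
        Convergence on the relative REML log-likelihood change.
    variance_floor : float
        Lower bound for each variance component, relative to var(y); a
        component at the floor is reported as effectively zero.
    fixed_components : mapping or None
        If a complete {term name: variance} mapping is given, no optimization
        is performed; BLUEs/BLUPs are computed at these values.

    Fitted attributes
    -----------------
    varcomp_ : dict        variance components on the response scale
    loglik_ : float        REML log-likelihood at the optimum
    converged_ : bool
    n_iter_ : int
    beta_ : pd.Series      fixed-effect BLUEs
    beta_se_ : pd.Series
    blup_ : dict           term name -> pd.Series of BLUPs
    pev_ : dict            term name -> pd.DataFrame, full PEV matrix
    dropped_fixed_ : list  aliased fixed-effect columns removed
    """

    def __init__(
        self,
        spec: ModelSpec,
        max_iter: int = 200,
        grad_tol: float = 1e-8,
        ll_tol: float = 1e-10,
        variance_floor: float = 1e-8,
        fixed_components: Optional[Mapping[str, float]] = None,
    ):
        self.spec = spec
        self.max_iter = max_iter
        self.grad_tol = grad_tol
        self.ll_tol = ll_tol
        self.variance_floor = variance_floor
        self.fixed_components = fixed_components

    # -- design construction ------------------------------------------------

    def _build_fixed(self, data: pd.DataFrame) -> tuple[list[str], np.ndarray]:
        spec = self.spec
        names: list[str] = []
        cols: list[np.ndarray] = []
        if spec.cell_means is not None:
            levels, Z = _dummies(data[spec.cell_means])
            names += [f"{spec.cell_means}[{l}]" for l in levels]
            cols.append(Z)
        elif spec.intercept:
            names.append("(Intercept)")
            cols.append(np.ones((len(data), 1)))
        for f in spec.fixed:
            if f == spec.cell_means:
                continue
            levels, Z = _dummies(data[f])
            names += [f"{f}[{l}]" for l in levels]
            cols.append(Z)
        X = np.hstack(cols) if cols else np.ones((len(data), 1))
        if not cols:
            names = ["(Intercept)"]
        keep = _sequential_rank_keep(X)
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        if dropped:
            logger.info("dropped aliased fixed-effect columns: %s", dropped)
        return [names[j] for j in keep], X[:, keep], dropped

    def _build_random(self, data: pd.DataFrame):
        """Return (names, G_list, blup_info) with residual appended last."""
        n = len(data)
        names, Gs, info = [], [], []
        for term in self.spec.random:
            if isinstance(term, RandomFactor):
                levels, Z = _dummies(data[term.factor])
                K = (
                    _align_kernel(term.kernel, levels, term.factor)
                    if term.kernel is not None
                    else None
                )
                G = Z @ K @ Z.T if K is not None else Z @ Z.T
                info.append({"Z": Z, "K": K, "levels": levels})
            elif isinstance(term, HadamardTerm):
                la, Za = _dummies(data[term.factor_a])
                lb, Zb = _dummies(data[term.factor_b])
                Kb = (
                    _align_kernel(term.kernel_b, lb, term.factor_b)
                    if term.kernel_b is not None
                    else None
                )
                Gb = Zb @ Kb @ Zb.T if Kb is not None else Zb @ Zb.T
                G = (Za @ Za.T) * Gb
                info.append(None)  # observation-level BLUPs not extracted
            else:  # pragma: no cover - guarded by ModelSpec
                raise DataError(f"unknown random term {term!r}")
            names.append(term.name)
            Gs.append(G)
        names.append("residual")
        Gs.append(np.eye(n))
        info.append(None)
        return names, Gs, info

    # -- REML criterion -----------------------------------------------------

    @staticmethod
    def _reml_pieces(y, X, Gs, sig):
        """Return (loglik, P, Py) for variance vector sig; None if V singular."""
        n, p = X.shape
        V = np.zeros((n, n))
        for s, G in zip(sig, Gs):
            V += s * G
        try:
            cf = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vinv = linalg.cho_solve(cf, np.eye(n), check_finite=False)
        XtVinv = X.T @ Vinv
        C = XtVinv @ X
        try:
            cfc = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdetC = 2.0 * np.sum(np.log(np.diag(cfc[0])))
        P = Vinv - XtVinv.T @ linalg.cho_solve(cfc, XtVinv, check_finite=False)
        Py = P @ y
        ll = -0.5 * (
            (n - p) * np.log(2.0 * np.pi) + logdetV + logdetC + float(y @ Py)
        )
        return ll, P, Py

    def _optimize(self, y, X, Gs, names):
        """AI-REML on the scaled response; y must have variance ~ 1."""
        k = len(Gs)
        n = len(y)
        floor = self.variance_floor
        sig = np.full(k, max(float(np.var(y, ddof=0)), 1.0) / k)
        sig = np.maximum(sig, floor)
        out = self._reml_pieces(y, X, Gs, sig)
        if out is None:
            raise ConvergenceError("initial covariance matrix is singular")
        ll, P, Py = out
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            GPy = [G @ Py for G in Gs]
            score = np.array(
                [
                    -0.5 * (float(np.sum(P * G)) - float(Py @ g))
                    for G, g in zip(Gs, GPy)
                ]
            )
            # KKT-aware gradient: a floored component with negative score is
            # at its optimum on the boundary. The tolerance scales with n
            # because the score is a sum over observations.
            eff = np.where((sig <= floor * 1.0001) & (score < 0), 0.0, score)
            if np.max(np.abs(eff)) < self.grad_tol * max(1.0, n):
                converged = True
                break
            PGPy = [P @ g for g in GPy]
            AI = 0.5 * np.array(
                [[float(GPy[i] @ PGPy[j]) for j in range(k)] for i in range(k)]
            )
            AI += np.eye(k) * (1e-10 + 1e-8 * np.trace(AI) / k)
            # solve on the free components only; boundary components with a
            # negative score stay pinned at the floor
            free = ~((sig <= floor * 1.0001) & (score < 0))
            delta = np.zeros(k)
            if free.any():
                AIf = AI[np.ix_(free, free)]
                try:
                    delta[free] = np.linalg.solve(AIf, score[free])
                except np.linalg.LinAlgError:
                    delta[free] = score[free] / np.maximum(np.diag(AIf), 1e-12)
            # trust region: variances live on an O(1) scale here, so cap the
            # step length (a near-singular AI matrix can give a huge delta)
            dmax = np.max(np.abs(delta))
            if dmax > 1.0:
                delta = delta / dmax
            step = 1.0
            accepted = False
            for _ in range(16):
                cand = np.maximum(sig + step * delta, floor)
                out = self._reml_pieces(y, X, Gs, cand)
                if out is not None and out[0] >= ll - 1e-10 * (1.0 + abs(ll)):
                    new_ll, P_new, Py_new = out
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                # fixed-point fallback keeps positivity and tends uphill
                num = np.array([float(Py @ g) for g in GPy])
                den = np.array([float(np.sum(P * G)) for G in Gs])
                ratio = np.sqrt(
                    np.clip(num / np.maximum(den, 1e-300), 0.01, 100.0)
                )
                cand = np.maximum(sig * ratio, floor)
                out = self._reml_pieces(y, X, Gs, cand)
                if out is None or out[0] < ll - 1e-8 * (1.0 + abs(ll)):
                    # no improving direction left: a numerical plateau at the
                    # (possibly boundary) optimum counts as converged
                    converged = np.max(np.abs(eff)) < 1e-4 * max(1.0, n)
                    break
                new_ll, P_new, Py_new = out
            if abs(new_ll - ll) < self.ll_tol * (1.0 + abs(ll)):
                sig, ll, P, Py = cand, new_ll, P_new, Py_new
                converged = True
                break
            sig, ll, P, Py = cand, new_ll, P_new, Py_new
        return sig, ll, converged, it

    # -- public API ---------------------------------------------------------

    def fit(self, data: pd.DataFrame, y=None):
        spec = self.spec
        if not isinstance(data, pd.DataFrame) or len(data) == 0:
            raise DataError("fit requires a non-empty DataFrame")
        if spec.response not in data.columns:
            raise DataError(f"response column {spec.response!r} not in data")
        yv = data[spec.response].to_numpy(dtype=float)
        if not np.all(np.isfinite(yv)):
            raise DataError("response contains non-finite values")
        for term in spec.random:
            facs = (
                [term.factor]
                if isinstance(term, RandomFactor)
                else [term.factor_a, term.factor_b]
            )
            for f in facs:
                if f not in data.columns:
                    raise DataError(f"random factor {f!r} not in data")
        for f in spec.fixed:
            if f not in data.columns:
                raise DataError(f"fixed factor {f!r} not in data")

        names_x, X, dropped = self._build_fixed(data)
        n, p = X.shape
        if n - p < 1:
            raise DataError(f"no residual degrees of freedom (n={n}, rank(X)={p})")
        rnames, Gs, info = self._build_random(data)

        sd = float(np.std(yv, ddof=0))
        if sd <= 0:
            sd = 1.0
        ys = yv / sd

        if self.fixed_components is not None:
            missing = [nm for nm in rnames if nm not in self.fixed_components]
            if missing:
                raise DataError(f"fixed_components missing terms: {missing}")
            sig = np.array([self.fixed_components[nm] for nm in rnames]) / sd**2
            sig = np.maximum(sig, self.variance_floor)
            out = self._reml_pieces(ys, X, Gs, sig)
            if out is None:
                raise DataError("supplied variance components give singular V")
            ll, _, _ = out
            converged, it = True, 0
        else:
            sig, ll, converged, it = self._optimize(ys, X, Gs, rnames)
            if not converged:
                warnings.warn(
                    "REML did not converge within max_iter; fit flagged",
                    RuntimeWarning,
                )

        # final pass on the original scale for reporting
        sig_orig = sig * sd**2
        out = self._reml_pieces(yv, X, Gs, np.maximum(sig_orig, 1e-300))
        if out is None:  # pragma: no cover - floor keeps V PD
            raise ConvergenceError("final covariance matrix is singular")
        ll_orig, P, Py = out

        V = np.zeros((n, n))
        for s, G in zip(sig_orig, Gs):
            V += s * G
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        Vinv = linalg.cho_solve(cf, np.eye(n), check_finite=False)
        XtVinv = X.T @ Vinv
        C = XtVinv @ X
        Cinv = np.linalg.inv(C)
        beta = Cinv @ (XtVinv @ yv)

        floor_orig = self.variance_floor * sd**2
        self.varcomp_ = {
            nm: (0.0 if s <= floor_orig * 1.0001 else float(s))
            for nm, s in zip(rnames, sig_orig)
        }
        self.varcomp_raw_ = dict(zip(rnames, sig_orig.tolist()))
        self.loglik_ = float(ll_orig)
        self.converged_ = bool(converged)
        self.n_iter_ = int(it)
        self.n_obs_ = int(n)
        self.dropped_fixed_ = dropped
        self.beta_ = pd.Series(beta, index=names_x)
        self.beta_se_ = pd.Series(np.sqrt(np.maximum(np.diag(Cinv), 0.0)), index=names_x)
        self.beta_cov_ = pd.DataFrame(Cinv, index=names_x, columns=names_x)

        self.blup_ = {}
        self.pev_ = {}
        for nm, s, inf in zip(rnames, sig_orig, info):
            if inf is None:
                continue
            Z, K, levels = inf["Z"], inf["K"], inf["levels"]
            KZt = (K @ Z.T) if K is not None else Z.T
            u = s * (KZt @ Py)
            PZ = P @ KZt.T
            Kmat = K if K is not None else np.eye(len(levels))
            pev = s * Kmat - s**2 * (KZt @ PZ)
            pev = 0.5 * (pev + pev.T)
            d = np.diag(pev).copy()
            np.fill_diagonal(pev, np.maximum(d, 0.0))
            self.blup_[nm] = pd.Series(u, index=levels)
            self.pev_[nm] = pd.DataFrame(pev, index=levels, columns=levels)
        return self


def fit_reml(data: pd.DataFrame, spec: ModelSpec, **kwargs) -> MixedModelREML:
    """Functional wrapper: fit ``spec`` to ``data`` and return the fitted model."""
    return MixedModelREML(spec, **kwargs).fit(data)


# --------------------------------------------------------------------------
# two-stage trial analysis
# --------------------------------------------------------------------------

PLOT_COLUMNS = ["genotype", "location", "year", "replicate", "row", "column", "yield"]


def stage1_blues(trial: pd.DataFrame) -> pd.DataFrame:
    """Single-trial genotype BLUEs.

    Genotype is fixed (cell means); replicate, row and column are i.i.d.
    random effects. Returns a table (location, year, genotype, blue, se).
    """
    missing = [c for c in PLOT_COLUMNS if c not in trial.columns]
    if missing:
        raise DataError(f"plot table missing columns: {missing}")
    trials = trial[["location", "year"]].drop_duplicates()
    if len(trials) != 1:
        raise DataError("stage1_blues expects exactly one trial (location x year)")
    if trial["replicate"].nunique() < 2:
        raise DataError("stage1_blues requires at least 2 replicates")
    spec = ModelSpec(
        response="yield",
        cell_means="genotype",
        random=(
            RandomFactor("replicate"),
            RandomFactor("row"),
            RandomFactor("column"),
        ),
    )
    fit = MixedModelREML(spec).fit(trial)
    levels = [nm[len("genotype[") : -1] for nm in fit.beta_.index]
    loc, yr = trials.iloc[0]["location"], trials.iloc[0]["year"]
    return pd.DataFrame(
        {
            "location": loc,
            "year": yr,
            "genotype": levels,
            "blue": fit.beta_.to_numpy(),
            "se": fit.beta_se_.to_numpy(),
        }
    )


def stage1_all_trials(plots: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`stage1_blues` to every (location, year) trial."""
    out = [
        stage1_blues(g)
        for _, g in plots.groupby(["location", "year"], sort=True)
    ]
    if not out:
        raise DataError("no trials found in plot table")
    return pd.concat(out, ignore_index=True)


_STAGE2_VARIANTS = ("MET", "MET_EC", "WC", "OPT")


def stage2_fit(
    blues: pd.DataFrame,
    variant: str = "MET",
    kernel: Optional[pd.DataFrame] = None,
    subset: Optional[Sequence[str]] = None,
    **fit_kwargs,
) -> MixedModelREML:
    """Multi-trial BLUP model on stage-1 BLUEs (evaluation scenarios).

    Fixed: year and environment-in-year (trial); random: genotype and GxE
    with identity (MET/WC/OPT) or supplied-kernel (MET_EC) environment
    covariance. ``subset`` restricts to a location list (WC/OPT scenarios).
    The second stage is unweighted by default (stage-1 SEs are not carried).
    """
    if variant not in _STAGE2_VARIANTS:
        raise DataError(f"unknown stage-2 variant {variant!r}")
    for c in ("location", "year", "genotype", "blue"):
        if c not in blues.columns:
            raise DataError(f"BLUE table missing column {c!r}")
    df = blues.copy()
    df["location"] = df["location"].astype(str)
    if variant in ("WC", "OPT"):
        if subset is None:
            raise DataError(f"variant {variant} requires a location subset")
        subset = [str(s) for s in subset]
        df = df[df["location"].isin(subset)]
    elif subset is not None:
        raise DataError("subset is only valid for WC/OPT variants")
    if df["location"].nunique() < 2:
        raise DataError("stage-2 fit requires BLUEs from at least 2 environments")
    df["trial"] = df["location"] + ":" + df["year"].astype(str)

    if variant == "MET_EC":
        if kernel is None:
            raise DataError("variant MET_EC requires an environment kernel")
        k_ids = {str(i) for i in kernel.index}
        envs = set(df["location"])
        if not envs <= k_ids:
            raise DataError(
                f"kernel does not cover environments: {sorted(envs - k_ids)[:5]}"
            )
        gxe = HadamardTerm("genotype", "location", kernel_b=kernel)
    else:
        if kernel is not None:
            raise DataError("kernel is only valid for variant MET_EC")
        gxe = HadamardTerm("genotype", "location")

    spec = ModelSpec(
        response="blue",
        fixed=("year", "trial"),
        random=(RandomFactor("genotype"), gxe),
    )
    return MixedModelREML(spec, **fit_kwargs).fit(df)


def cullis_h2(
    fit: MixedModelREML, term: str = "genotype", vbar: str = "pair_difference"
) -> float:
    """Cullis broad-sense heritability H2 = 1 - vbar_delta / (2 s2_g).

    vbar="pair_difference" (default) uses the mean variance of a difference
    between genotype BLUPs computed from the full PEV matrix. The alternative
    vbar="mean_pev" substitutes the mean PEV of the BLUPs into the same
    formula.
    """
    if term not in fit.pev_:
        raise DataError(f"fit has no PEV matrix for random term {term!r}")
    s2g = fit.varcomp_.get(term, 0.0)
    if s2g <= 0.0:
        warnings.warn("genotypic variance is zero; H2 defined as 0", RuntimeWarning)
        return 0.0
    C = fit.pev_[term].to_numpy()
    q = C.shape[0]
    if q < 2:
        raise DataError("Cullis H2 requires at least 2 genotypes")
    if vbar == "pair_difference":
        v = 2.0 * (q * np.trace(C) - C.sum()) / (q * (q - 1))
    elif vbar == "mean_pev":
        v = float(np.trace(C) / q)
    else:
        raise DataError(f"unknown vbar method {vbar!r}")
    h2 = 1.0 - v / (2.0 * s2g)
    if h2 < 0.0 or h2 > 1.0:
        logger.info("Cullis H2 = %.4f clipped into [0, 1]", h2)
    return float(np.clip(h2, 0.0, 1.0))


def variance_partition(blues: pd.DataFrame, **fit_kwargs) -> pd.DataFrame:
    """All-random multi-trial model: year, genotype, environment, GxE, residual.

    Returns a table with variance components and proportions (summing to 1).
    """
    for c in ("location", "year", "genotype", "blue"):
        if c not in blues.columns:
            raise DataError(f"BLUE table missing column {c!r}")
    df = blues.copy()
    df["location"] = df["location"].astype(str)
    df["trial"] = df["location"] + ":" + df["year"].astype(str)
    spec = ModelSpec(
        response="blue",
        random=(
            RandomFactor("year"),
            RandomFactor("genotype"),
            RandomFactor("trial"),
            HadamardTerm("genotype", "location"),
        ),
    )
    fit = MixedModelREML(spec, **fit_kwargs).fit(df)
    comp = pd.Series(fit.varcomp_)
    total = comp.sum()
    if total <= 0:
        raise DataError("all variance components are zero")
    return pd.DataFrame({"variance": comp, "proportion": comp / total})
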