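"""Enviromic and yield-based environment relationship kernels.

The enviromic kernel is Omega = W W' / (tr(W W') / n_env), computed from the
centered/scaled environment x covariate matrix W; by construction it is
symmetric, positive semidefinite and has trace equal to the number of
environments. The yield-based counterpart applies the same normalization to
the environment x genotype matrix of stage-1 BLUEs (columns centered and
scaled over environments). Kernels are compared by the Pearson correlation
of their off-diagonal entries and by kernel-density summaries (Silverman
bandwidth).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError

logger = logging.getLogger(__name__)

__all__ = ["EnvKernel", "KernelComparison", "env_kernel", "yield_kernel", "compare_kernels"]


@dataclass
class EnvKernel:
    """Environment similarity matrix with trace = n_env normalization."""

    matrix: pd.DataFrame
    provenance: str  # "enviromic" | "yield"

    def __post_init__(self):
        M = self.matrix.to_numpy(dtype=float)
        if M.shape[0] != M.shape[1]:
            raise DataError("kernel must be square")
        if not np.allclose(M, M.T, atol=1e-10):
            raise DataError("kernel must be symmetric")
        w = np.linalg.eigvalsh(M)
        if w.min() < -1e-8:
            raise DataError(f"kernel must be PSD (min eigenvalue {w.min():.3g})")
        n = M.shape[0]
        if abs(np.trace(M) - n) > 1e-8:
            raise DataError("kernel trace must equal the number of environments")

    @property
    def environments(self) -> list:
        return list(self.matrix.index)

    def off_diagonal(self) -> np.ndarray:
        M = self.matrix.to_numpy()
        iu = np.triu_indices(M.shape[0], k=1)
        return M[iu]


@dataclass
class KernelComparison:
    """Pearson r over paired off-diagonals plus per-kernel density summaries."""

    pearson_r: float
    density_a: dict  # {"peak", "mean", "sd"}
    density_b: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "pearson_r": self.pearson_r,
                "density_a": self.density_a,
                "density_b": self.density_b,
            },
            indent=1,
        )


def _normalize(WWt: np.ndarray, index) -> pd.DataFrame:
    n = WWt.shape[0]
    tr = float(np.trace(WWt))
    if tr <= 0:
        raise DataError("cannot normalize a kernel with zero trace (all-zero W)")
    return pd.DataFrame(WWt / (tr / n), index=index, columns=index)


def env_kernel(W) -> EnvKernel:
    """Enviromic kernel Omega = W W' / (tr(W W')/n_env) from the W matrix."""
    Wdf = W.values if hasattr(W, "values") and isinstance(getattr(W, "values"), pd.DataFrame) else pd.DataFrame(W)
    if Wdf.empty:
        raise DataError("W is empty")
    if Wdf.isna().any().any():
        raise DataError("W contains missing values")
    A = Wdf.to_numpy(dtype=float)
    return EnvKernel(matrix=_normalize(A @ A.T, Wdf.index), provenance="enviromic")


def yield_kernel(blues: pd.DataFrame) -> EnvKernel:
    """Yield-based kernel Omega_yield from the environment x genotype BLUEs.

    Cells with a genotype untested in an environment are imputed with the
    genotype's mean BLUE (logged). Genotype columns are centered and scaled
    over environments before the trace normalization.
    """
    for c in ("location", "genotype", "blue"):
        if c not in blues.columns:
            raise DataError(f"BLUE table missing column {c!r}")
    wide = blues.pivot_table(index="location", columns="genotype", values="blue", aggfunc="mean")
    wide.index = wide.index.astype(str)
    if wide.shape[0] < 2:
        raise DataError("yield kernel requires at least 2 environments")
    complete = wide.dropna(axis=1)
    if complete.shape[1] < 2:
        raise DataError("yield kernel requires at least 2 genotypes common to all environments")
    n_missing = int(wide.isna().sum().sum())
    if n_missing:
        logger.info("imputing %d genotype x environment cells with genotype means", n_missing)
        wide = wide.fillna(wide.mean())
    sd = wide.std(ddof=1)
    dead = list(sd.index[(sd == 0) | sd.isna()])
    if dead:
        logger.warning("dropping zero-variance genotype columns: %s", dead)
        wide = wide.drop(columns=dead)
        sd = sd.drop(dead)
    Wy = (wide - wide.mean()) / sd
    A = Wy.to_numpy(dtype=float)
    return EnvKernel(matrix=_normalize(A @ A.T, Wy.index), provenance="yield")


def compare_kernels(a: EnvKernel, b: EnvKernel, grid_points: int = 512) -> KernelComparison:
    """Pearson correlation and KDE summaries of two kernels' off-diagonals."""
    if a.environments != b.environments:
        raise DataError("kernels must share the same environment set and order")

    def density(x: np.ndarray) -> dict:
        x = np.asarray(x, dtype=float)
        mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if sd == 0:
            return {"peak": mean, "mean": mean, "sd": 0.0}
        kde = stats.gaussian_kde(x, bw_method="silverman")
        bw = kde.factor * sd
        grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_points)
        peak = float(grid[np.argmax(kde(grid))])
        return {"peak": peak, "mean": mean, "sd": sd}

    xa, xb = a.off_diagonal(), b.off_diagonal()
    if len(xa) < 2:
        raise DataError("need at least 2 environments to compare kernels")
    r = float(stats.pearsonr(xa, xb)[0])
    return KernelComparison(pearson_r=r, density_a=density(xa), density_b=density(xb))
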