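"""Supervised covariate selection: recursive feature elimination (RFE).

A random-forest learner is wrapped in repeated K-fold cross-validation over
environments. Within every training fold the forest is refit while features
are eliminated stepwise down a grid of candidate subset sizes, ranking by
impurity importance at each step; held-out predictions are pooled per repeat
and scored as R². The subset size with the best mean CV R² is refit on all
environments to produce the final selection.

The response is the per-environment mean of stage-1 genotype BLUEs, so the
headline CV R² reads as the share of yield variation across sites explained
by the selected covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import RepeatedKFold

from .exceptions import ConfigError, DataError

__all__ = ["RfeResult", "RfeSelector", "rfe_select", "default_size_grid"]

_DEFAULT_GRID = (2, 4, 6, 8, 10, 12, 16, 24, 32)


def default_size_grid(n_features: int) -> list[int]:
    """{2,4,6,8,10,12,16,24,32} clipped to the feature count, plus 'all'."""
    grid = sorted({s for s in _DEFAULT_GRID if s < n_features} | {n_features})
    return grid


@dataclass
class RfeResult:
    """Outcome of RFE: selection, CV trace, importances and configuration."""

    selected: list
    chosen_size: int
    cv_r2: dict  # size -> mean R2 over repeats (pooled out-of-fold)
    cv_r2_sd: dict  # size -> SD over repeats
    importances: pd.Series  # final model, selected covariates
    train_r2: float  # final model refit on all environments
    folds: int
    repeats: int
    seed: int
    n_estimators: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected": list(self.selected),
                "chosen_size": int(self.chosen_size),
                "cv_r2": {str(k): float(v) for k, v in self.cv_r2.items()},
                "cv_r2_sd": {str(k): float(v) for k, v in self.cv_r2_sd.items()},
                "importances": {k: float(v) for k, v in self.importances.items()},
                "train_r2": float(self.train_r2),
                "cv": {"folds": self.folds, "repeats": self.repeats},
                "seed": int(self.seed),
                "n_estimators": int(self.n_estimators),
            },
            indent=1,
        )


class RfeSelector(BaseEstimator):
    """Sklearn-style RFE selector over environment covariates.

    Fitted attributes: ``selected_features_``, ``chosen_size_``,
    ``cv_scores_`` (size -> mean R²), ``cv_scores_sd_``, ``importances_``,
    ``train_r2_``, ``result_`` (an :class:`RfeResult`).
    """

    def __init__(
        self,
        folds: int = 5,
        repeats: int = 5,
        subset_sizes: Optional[Sequence[int]] = None,
        n_estimators: int = 500,
        random_state: int = 0,
    ):
        self.folds = folds
        self.repeats = repeats
        self.subset_sizes = subset_sizes
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _rf(self, seed: int) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_estimators, random_state=seed, n_jobs=1
        )

    def _eliminate(self, Xt, yt, sizes_desc, seeds):
        """Stepwise elimination; returns {size: (features, model)}."""
        feats = list(Xt.columns)
        out = {}
        last_model = None
        for s, seed in zip(sizes_desc, seeds):
            if s < len(feats):
                imp = pd.Series(last_model.feature_importances_, index=feats)
                feats = list(imp.sort_values(ascending=False, kind="stable").index[:s])
            model = self._rf(seed).fit(Xt[feats], yt)
            last_model = model
            out[s] = (list(feats), model)
        return out

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        n, p = X.shape
        if n < self.folds:
            raise DataError(f"need at least folds={self.folds} environments, got {n}")
        sizes = (
            sorted({int(s) for s in self.subset_sizes})
            if self.subset_sizes is not None
            else default_size_grid(p)
        )
        if not sizes:
            raise ConfigError("subset_sizes is empty")
        if sizes[0] < 1 or sizes[-1] > p:
            raise ConfigError("subset sizes must lie in [1, n_features]")
        sizes_desc = sorted(sizes, reverse=True)
        if sizes_desc[0] < p:
            sizes_desc = [p] + sizes_desc  # always start elimination from all

        seed_seq = np.random.SeedSequence(self.random_state)
        rkf = RepeatedKFold(
            n_splits=self.folds, n_repeats=self.repeats, random_state=self.random_state
        )
        preds = {s: np.full((self.repeats, n), np.nan) for s in sizes}
        split_seeds = seed_seq.spawn(self.folds * self.repeats + 1)
        for split_i, (tr, te) in enumerate(rkf.split(X)):
            rep = split_i // self.folds
            fold_seeds = split_seeds[split_i].generate_state(len(sizes_desc)) % (2**31)
            models = self._eliminate(X.iloc[tr], y.iloc[tr], sizes_desc, fold_seeds)
            for s in sizes:
                feats, model = models[s]
                preds[s][rep, te] = model.predict(X.iloc[te][feats])

        cv_r2, cv_sd = {}, {}
        for s in sizes:
            per_rep = [r2_score(y, preds[s][rep]) for rep in range(self.repeats)]
            cv_r2[s] = float(np.mean(per_rep))
            cv_sd[s] = float(np.std(per_rep, ddof=1)) if self.repeats > 1 else 0.0

        chosen = min(sizes, key=lambda s: (-cv_r2[s], s))
        final_seeds = split_seeds[-1].generate_state(len(sizes_desc)) % (2**31)
        final = self._eliminate(X, y, sizes_desc, final_seeds)
        feats, model = final[chosen]
        self.selected_features_ = feats
        self.chosen_size_ = chosen
        self.cv_scores_ = cv_r2
        self.cv_scores_sd_ = cv_sd
        self.importances_ = pd.Series(model.feature_importances_, index=feats)
        self.train_r2_ = float(r2_score(y, model.predict(X[feats])))
        self.result_ = RfeResult(
            selected=feats,
            chosen_size=chosen,
            cv_r2=cv_r2,
            cv_r2_sd=cv_sd,
            importances=self.importances_,
            train_r2=self.train_r2_,
            folds=self.folds,
            repeats=self.repeats,
            seed=self.random_state,
            n_estimators=self.n_estimators,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_features_]


def rfe_select(
    W: pd.DataFrame,
    env_response: pd.Series,
    folds: int = 5,
    repeats: int = 5,
    subset_sizes: Optional[Sequence[int]] = None,
    seed: int = 0,
    n_estimators: int = 500,
) -> RfeResult:
    """Functional wrapper around :class:`RfeSelector`.

    ``W`` rows and ``env_response`` must cover the same environments.
    """
    W = getattr(W, "values", W) if not isinstance(W, pd.DataFrame) else W
    env_response = pd.Series(env_response)
    env_response.index = env_response.index.astype(str)
    Wdf = pd.DataFrame(W)
    Wdf.index = Wdf.index.astype(str)
    missing = [e for e in Wdf.index if e not in set(env_response.index)]
    if missing:
        raise DataError(f"response missing environments: {missing[:5]}")
    y = env_response.loc[Wdf.index]
    sel = RfeSelector(
        folds=folds,
        repeats=repeats,
        subset_sizes=subset_sizes,
        n_estimators=n_estimators,
        random_state=seed,
    ).fit(Wdf, y)
    return sel.result_
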