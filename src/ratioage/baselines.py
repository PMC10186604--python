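"""Normalization x learner screening grid and bootstrap RMSE comparison.

The screening asks a blunt question — does any off-the-shelf regressor on any
normalized version of the table beat the rest? — before committing to the
ratio network.  Learners are pluggable scikit-learn regressors tuned by
k-fold cross-validation on the train+development partition only; the test
partition is touched exactly once per grid cell, for the final RMSE.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import GridSearchCV

from .preprocessing import SplitSpec, impute_missing
from .ratio_net import rmse
from .table import FeatureTable

logger = logging.getLogger(__name__)

TUNE_LENGTH = 5  # candidate values per tuned hyperparameter


def default_learners(seed: int = 0, tune_length: int = TUNE_LENGTH) -> dict:
    """The screening lineup: (estimator, parameter grid) per learner name.

    Covers a mean-only reference, ordinary and penalized linear models, a
    latent-projection model, bagged trees and boosted trees — off-the-shelf
    implementations, deliberately not tuned beyond a small grid.
    """
    alphas = np.logspace(-4, 1, tune_length)
    return {
        "mean": (DummyRegressor(strategy="mean"), {}),
        "linear": (LinearRegression(), {}),
        "enet": (
            ElasticNet(max_iter=5000, random_state=seed),
            {"alpha": alphas, "l1_ratio": np.linspace(0.1, 0.9, tune_length)},
        ),
        "pls": (
            PLSRegression(scale=False),
            {"n_components": [2, 4, 8, 12, 16][:tune_length]},
        ),
        "rf": (
            RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1),
            {"max_features": [0.1, 0.3, 0.5, 0.7, 1.0][:tune_length]},
        ),
        "gbt": (
            HistGradientBoostingRegressor(random_state=seed),
            {"learning_rate": np.logspace(-2, 0, tune_length)},
        ),
    }


@dataclass
class ScreenResult:
    """Grid of test RMSEs (years) over (normalization, learner) pairs."""

    grid: pd.DataFrame  # index: normalization name, columns: learner name
    folds: int
    seeds: dict = field(default_factory=dict)
    best_params: dict = field(default_factory=dict)

    @property
    def best(self) -> tuple[str, str, float]:
        """(normalization, learner, rmse) of the best grid cell."""
        cell = self.grid.stack().idxmin()
        return cell[0], cell[1], float(self.grid.loc[cell])

    def to_csv(self, path) -> None:
        self.grid.to_csv(path)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "grid": self.grid.to_dict(orient="index"),
                    "folds": self.folds,
                    "seeds": self.seeds,
                    "best_params": self.best_params,
                },
                fh,
                indent=1,
                default=str,
            )


def _xy(table: FeatureTable, ids) -> tuple[np.ndarray, np.ndarray]:
    sub = table.select_samples(ids)
    return sub.values(), sub.ages.to_numpy(dtype=float)


def screen_models(
    datasets: dict[str, FeatureTable],
    split: SplitSpec,
    learners: dict | None = None,
    folds: int = 5,
    seed: int = 0,
) -> ScreenResult:
    """Fill the (normalization, learner) grid with held-out test RMSEs.

    Per cell: hyperparameters tuned by ``folds``-fold CV on train+dev, model
    refit on train+dev with the best settings, RMSE measured on the test ids.
    A failing learner marks its cell NaN and the run continues.
    """
    learners = learners if learners is not None else default_learners(seed)
    grid = pd.DataFrame(
        np.nan, index=list(datasets), columns=list(learners), dtype=float
    )
    best_params: dict = {}
    tune_ids = list(split.train_ids) + list(split.dev_ids)
    for norm_name, table in datasets.items():
        table = impute_missing(table)
        x_tune, y_tune = _xy(table, tune_ids)
        x_test, y_test = _xy(table, split.test_ids)
        for learner_name, (estimator, param_grid) in learners.items():
            try:
                if param_grid:
                    search = GridSearchCV(
                        clone(estimator), param_grid, cv=folds,
                        scoring="neg_root_mean_squared_error", n_jobs=1,
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        search.fit(x_tune, y_tune)
                    model = search.best_estimator_
                    best_params[f"{norm_name}/{learner_name}"] = search.best_params_
                else:
                    model = clone(estimator).fit(x_tune, y_tune)
                pred = np.asarray(model.predict(x_test)).ravel()
                grid.loc[norm_name, learner_name] = rmse(pred, y_test)
            except Exception as exc:  # a failed cell must not kill the screen
                logger.warning("cell (%s, %s) failed: %s", norm_name, learner_name, exc)
                grid.loc[norm_name, learner_name] = np.nan
    return ScreenResult(grid=grid, folds=folds, seeds={"seed": seed},
                        best_params=best_params)


def bootstrap_rmse_compare(
    pred_a, pred_b, truth, n_boot: int = 1000, seed: int = 0
) -> dict:
    """Paired bootstrap of RMSE(a) - RMSE(b) on shared test samples.

    Resamples test indices with replacement; returns the mean difference and
    the 2.5/97.5 percentile interval.  Negative values favour model a.
    """
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if not (len(pred_a) == len(pred_b) == len(truth)) or len(truth) == 0:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile intervals")
    rng = np.random.default_rng(seed)
    n = len(truth)
    idx = rng.integers(0, n, size=(n_boot, n))
    sq_a = (pred_a - truth) ** 2
    sq_b = (pred_b - truth) ** 2
    delta = np.sqrt(sq_a[idx].mean(axis=1)) - np.sqrt(sq_b[idx].mean(axis=1))
    lo, hi = np.percentile(delta, [2.5, 97.5])
    return {
        "mean_delta_rmse": float(delta.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_boot": int(n_boot),
    }
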