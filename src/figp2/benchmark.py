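"""Comparison protocol: baselines, the execution matrix, relative RMSE.

Every method in a cell of the experiment matrix — a (feature set,
train ratio, split) triple — sees the identical train/test split.  Per
execution, each method's test RMSE is normalized by the mean predictor's
test RMSE on the same split; methods are then compared by the median of
those relative RMSEs (with 40th/60th-percentile bands).  The default
matrix is 3 feature sets x 3 train ratios x 5 splits = 45 executions per
method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .data import FEATURE_SETS, Dataset, FeatureSet, split_train_test
from .engine import GPConfig, InitializationError, preset_config
from .estimator import SymbolicRegressor

__all__ = [
    "ExperimentMatrix",
    "MethodResult",
    "mean_predictor",
    "fit_mlr",
    "fit_svr_rbf",
    "run_matrix",
    "summarize",
    "GP_METHODS",
]

GP_METHODS = ("GP", "FIGP", "FIGP2_D2", "FIGP2")
ALL_METHODS = GP_METHODS + ("MLR", "SVR", "MEAN")


@dataclass
class ExperimentMatrix:
    """The (feature set, train ratio, split) execution grid."""

    feature_sets: tuple = tuple(FEATURE_SETS.values())
    train_ratios: tuple[float, ...] = (0.2, 0.5, 0.8)
    n_splits: int = 5
    base_seed: int = 0

    @property
    def n_executions(self) -> int:
        return len(self.feature_sets) * len(self.train_ratios) * self.n_splits

    def cells(self):
        for fs in self.feature_sets:
            fs = fs if isinstance(fs, FeatureSet) else FeatureSet(
                ",".join(fs), tuple(fs)
            )
            for ratio in self.train_ratios:
                for split in range(self.n_splits):
                    seed = self.base_seed + 1000 * split + round(100 * ratio)
                    yield fs, ratio, split, seed


@dataclass
class MethodResult:
    method: str
    rmse_values: list = field(default_factory=list)
    relative_values: list = field(default_factory=list)

    @property
    def median_rmse(self) -> float:
        return float(np.median(self.rmse_values))

    @property
    def relative_rmse(self) -> float:
        return float(np.median(self.relative_values))


def mean_predictor(train_y):
    """Baseline that always predicts the training mean."""
    y = np.asarray(train_y, dtype=float)
    model = DummyRegressor(strategy="mean")
    model.fit(np.zeros((len(y), 1)), y)
    return model


def fit_mlr(X, y):
    """Ordinary least-squares linear model on the active feature set."""
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([Xa, np.ones(len(Xa))])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "design matrix is rank-deficient; try a smaller feature set"
        )
    return LinearRegression().fit(Xa, y)


def fit_svr_rbf(
    X,
    y,
    cv_folds: int = 5,
    C_grid=(0.1, 1.0, 10.0, 100.0, 1000.0),
    epsilon_grid=(0.01, 0.1, 0.5, 1.0),
    gamma_grid=(1e-3, 1e-2, 0.1, 1.0, 10.0),
    seed: int = 0,
):
    """RBF-kernel support vector regression with CV-selected C, epsilon, gamma.

    Features are standardized (training mean/std) inside the pipeline; the
    grid search minimizes cross-validated RMSE with a seeded fold
    assignment.  The fitted search exposes ``best_params_``.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < cv_folds:
        raise ValueError(f"need at least {cv_folds} rows for {cv_folds}-fold CV")
    pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
    grid = {
        "svr__C": list(C_grid),
        "svr__epsilon": list(epsilon_grid),
        "svr__gamma": list(gamma_grid),
    }
    search = GridSearchCV(
        pipe,
        grid,
        cv=KFold(cv_folds, shuffle=True, random_state=seed),
        scoring="neg_root_mean_squared_error",
        n_jobs=1,
    )
    return search.fit(np.asarray(X, dtype=float), y)


def _rmse(pred, y) -> float:
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def _fit_predict(method, train: Dataset, test: Dataset, cfg: GPConfig, seed: int):
    """Fit one method on the training split; return (test predictions, fallback)."""
    Xtr, ytr = train.X, np.asarray(train.y, dtype=float)
    Xte = test.X
    if method == "MEAN":
        return mean_predictor(ytr).predict(np.zeros((len(Xte), 1))), False
    if method == "MLR":
        return fit_mlr(Xtr, ytr).predict(np.asarray(Xte, dtype=float)), False
    if method == "SVR":
        return (
            fit_svr_rbf(Xtr, ytr, cv_folds=min(5, len(ytr)), seed=seed).predict(
                np.asarray(Xte, dtype=float)
            ),
            False,
        )
    if method in GP_METHODS:
        run_cfg = preset_config(
            method,
            seed=seed,
            population_size=cfg.population_size,
            n_generations=cfg.n_generations,
            max_regen_attempts=cfg.max_regen_attempts,
        )
        est = SymbolicRegressor(
            population_size=run_cfg.population_size,
            n_generations=run_cfg.n_generations,
            filters=run_cfg.active_filters,
            fitness=run_cfg.stability.metric_kind,
            max_regen_attempts=run_cfg.max_regen_attempts,
            random_state=seed,
        )
        try:
            est.fit(Xtr, ytr)
        except InitializationError:
            # keep the cell's median defined: score as the mean predictor
            return np.full(len(Xte), float(np.mean(ytr))), True
        return est.predict(Xte), False
    raise ValueError(f"unknown method {method!r}")


def run_matrix(
    ds: Dataset,
    methods=ALL_METHODS,
    matrix: ExperimentMatrix | None = None,
    cfg: GPConfig | None = None,
) -> pd.DataFrame:
    """Run every method on every cell of the matrix over identical splits.

    Returns a tidy table (method, feature_set, train_ratio, split, seed,
    rmse, relative_rmse, fallback); relative RMSE is computed per execution
    against the mean predictor before any aggregation.
    """
    matrix = matrix or ExperimentMatrix()
    cfg = cfg or GPConfig()
    rows = []
    for fs, ratio, split, seed in matrix.cells():
        sub = ds.subset(fs)
        train, test = split_train_test(sub, ratio, seed=seed)
        yte = np.asarray(test.y, dtype=float)
        mean_rmse = _rmse(
            np.full(len(yte), float(np.mean(np.asarray(train.y, float)))), yte
        )
        for method in methods:
            pred, fallback = _fit_predict(method, train, test, cfg, seed)
            rmse = _rmse(pred, yte)
            rows.append(
                {
                    "method": method,
                    "feature_set": fs.name,
                    "train_ratio": ratio,
                    "split": split,
                    "seed": seed,
                    "rmse": rmse,
                    "relative_rmse": rmse / mean_rmse,
                    "fallback": fallback,
                }
            )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-method medians and 40th/60th-percentile bands of relative RMSE."""
    out = []
    for method, grp in results.groupby("method", sort=False):
        rel = grp["relative_rmse"].to_numpy()
        out.append(
            {
                "method": method,
                "n_executions": len(grp),
                "median_rmse": float(np.median(grp["rmse"])),
                "median_relative_rmse": float(np.median(rel)),
                "p40_relative_rmse": float(np.percentile(rel, 40)),
                "p60_relative_rmse": float(np.percentile(rel, 60)),
            }
        )
    return pd.DataFrame(out)
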