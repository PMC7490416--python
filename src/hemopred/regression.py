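"""Nested cross-validated regression study.

Protocol: rows are shuffled once (seeded) into ten outer folds; within each
outer fold an exhaustive grid search with ten inner folds (run only on the
outer-training rows) picks the hyperparameter combination with the lowest
mean inner MSE; a model with that setting is refit on the full outer-train
set and predicts the held-out rows.  Four model families are supported with
the study's fixed hyperparameter grids; unlisted hyperparameters stay at
scikit-learn defaults (SVR uses an RBF kernel with epsilon 0.1; features
enter on their raw scales — no standardisation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .dataset import FEATURE_COLUMNS, TARGET_COLUMNS, StudyDataset
from .errors import (
    AlignmentError,
    InvalidParameterError,
    ScenarioError,
    SweepError,
)

__all__ = [
    "DEFAULT_GRIDS",
    "ModelSpec",
    "ScenarioSpec",
    "CVConfig",
    "CVRunResult",
    "run_nested_cv",
    "ensemble_average",
    "hyperparameter_frequency",
    "training_size_sweep",
    "fit_full_and_predict_external",
]

#: The study's hyperparameter grids per model family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"max_depth": [5, 10, 20],
                      "n_estimators": [500, 700, 1000]},
    "svr": {"C": [1, 10, 100], "gamma": [0.001, 0.01, 0.1, 1]},
    "ridge": {"alpha": [1, 10, 100, 200]},
    "gradient_boosting": {"learning_rate": [0.01, 0.05, 1],
                          "n_estimators": [100, 500, 1000, 1750]},
}

_VALID_FEATURES = tuple(FEATURE_COLUMNS)
_VALID_TARGETS = tuple(TARGET_COLUMNS)


@dataclass(frozen=True)
class ModelSpec:
    """A regression family plus its hyperparameter grid."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise InvalidParameterError(
                f"unknown model family {self.family!r}; "
                f"expected one of {sorted(DEFAULT_GRIDS)}"
            )
        if not self.grid:
            object.__setattr__(self, "grid", dict(DEFAULT_GRIDS[self.family]))
        bad = set(self.grid) - set(DEFAULT_GRIDS[self.family])
        if bad:
            raise InvalidParameterError(
                f"invalid hyperparameters for {self.family}: {sorted(bad)}"
            )
        if any(len(v) == 0 for v in self.grid.values()):
            raise InvalidParameterError("empty hyperparameter candidate set")

    def make_estimator(self, params: dict, seed: int | None = None):
        if self.family == "random_forest":
            return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
        if self.family == "svr":
            return SVR(kernel="rbf", epsilon=0.1, cache_size=500, **params)
        if self.family == "ridge":
            return Ridge(**params)
        return GradientBoostingRegressor(random_state=seed, **params)

    def grid_points(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]


@dataclass(frozen=True)
class ScenarioSpec:
    """Which features predict which target."""

    features: tuple[str, ...]
    target: str

    def __post_init__(self) -> None:
        if not self.features:
            raise ScenarioError("scenario needs at least one feature")
        bad = set(self.features) - set(_VALID_FEATURES)
        if bad:
            raise ScenarioError(f"unknown features: {sorted(bad)}")
        if self.target not in _VALID_TARGETS:
            raise ScenarioError(f"unknown target: {self.target!r}")

    @property
    def feature_columns(self) -> list[str]:
        return [FEATURE_COLUMNS[f] for f in self.features]

    @property
    def target_column(self) -> str:
        return TARGET_COLUMNS[self.target]


#: The two headline scenarios: cuff surrogates alone, and EF-augmented.
PRESSURE_FEATURES = ("brSBP", "brDBP", "HR", "cfPWV")
PRESSURE_EF_FEATURES = ("brSBP", "brDBP", "HR", "cfPWV", "EF")


@dataclass(frozen=True)
class CVConfig:
    """Nested cross-validation protocol (outer evaluation, inner tuning)."""

    outer_folds: int = 10
    inner_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise InvalidParameterError("folds must be >= 2")


@dataclass
class CVRunResult:
    """Out-of-fold predictions and per-fold tuning records of one run."""

    model: ModelSpec
    scenario: ScenarioSpec
    cv: CVConfig
    y_true: np.ndarray
    y_pred: np.ndarray            # aligned with the dataset row order
    fold_ids: np.ndarray          # outer fold per row
    fold_params: list[dict]       # selected hyperparameters per outer fold
    fold_inner_mse: list[float]   # winning mean inner MSE per outer fold


def _design(dataset: StudyDataset | pd.DataFrame, scenario: ScenarioSpec,
            need_target: bool = True):
    table = dataset.table if isinstance(dataset, StudyDataset) else dataset
    cols = scenario.feature_columns + ([scenario.target_column] if need_target else [])
    for c in cols:
        if c not in table.columns:
            raise ScenarioError(f"dataset lacks column {c}")
    X = table[scenario.feature_columns].to_numpy(dtype=float)
    y = table[scenario.target_column].to_numpy(dtype=float) if need_target else None
    return X, y


def _grid_search(model: ModelSpec, X: np.ndarray, y: np.ndarray,
                 n_folds: int, seed: int,
                 forbidden_rows: np.ndarray | None = None):
    """Exhaustive grid search by mean MSE over seeded K-fold CV.

    ``forbidden_rows`` is a leakage guard: global row indices that must not
    appear in X/y (asserted by the caller passing the outer-test set).
    Ties break toward the earlier grid point (deterministic order).
    """
    points = model.grid_points()
    if len(points) == 1:
        return points[0], np.nan
    inner = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(inner.split(X))
    best_params, best_mse = None, np.inf
    for params in points:
        mse_sum = 0.0
        for tr, te in splits:
            est = model.make_estimator(params, seed=seed)
            est.fit(X[tr], y[tr])
            resid = est.predict(X[te]) - y[te]
            mse_sum += float(np.mean(resid ** 2))
        mse = mse_sum / len(splits)
        if mse < best_mse:
            best_mse, best_params = mse, params
    return best_params, best_mse


def run_nested_cv(dataset: StudyDataset, model: ModelSpec,
                  scenario: ScenarioSpec, cv: CVConfig | None = None,
                  progress: bool = False) -> CVRunResult:
    """Run the nested ten-by-ten CV protocol for one (model, scenario)."""
    cv = cv or CVConfig()
    X, y = _design(dataset, scenario)
    n = len(y)
    outer = KFold(n_splits=cv.outer_folds, shuffle=True, random_state=cv.seed)
    y_pred = np.full(n, np.nan)
    fold_ids = np.full(n, -1, dtype=int)
    fold_params: list[dict] = []
    fold_mse: list[float] = []
    for k, (tr, te) in enumerate(outer.split(X)):
        assert np.intersect1d(tr, te).size == 0  # leakage guard
        params, mse = _grid_search(
            model, X[tr], y[tr], cv.inner_folds, seed=cv.seed + 1000 + k
        )
        est = model.make_estimator(params, seed=cv.seed + 2000 + k)
        est.fit(X[tr], y[tr])
        y_pred[te] = est.predict(X[te])
        fold_ids[te] = k
        fold_params.append(params)
        fold_mse.append(mse)
        if progress:
            print(f"  outer fold {k + 1}/{cv.outer_folds}: {params}", flush=True)
    assert not np.any(np.isnan(y_pred)) and np.all(fold_ids >= 0)
    return CVRunResult(model=model, scenario=scenario, cv=cv, y_true=y,
                       y_pred=y_pred, fold_ids=fold_ids,
                       fold_params=fold_params, fold_inner_mse=fold_mse)


def ensemble_average(runs: list[CVRunResult]) -> np.ndarray:
    """Element-wise unweighted mean of aligned out-of-fold predictions."""
    if not runs:
        raise AlignmentError("no runs to average")
    ref = runs[0]
    for r in runs[1:]:
        if (len(r.y_pred) != len(ref.y_pred)
                or not np.array_equal(r.fold_ids, ref.fold_ids)
                or not np.array_equal(r.y_true, ref.y_true)):
            raise AlignmentError("runs differ in dataset or fold assignment")
    return np.mean([r.y_pred for r in runs], axis=0)


def hyperparameter_frequency(run: CVRunResult) -> pd.DataFrame:
    """Percent of outer folds in which each candidate value was selected."""
    rows = []
    n_folds = len(run.fold_params)
    for hp, candidates in run.model.grid.items():
        for value in candidates:
            count = sum(1 for p in run.fold_params if p[hp] == value)
            rows.append({"hyperparameter": hp, "value": value,
                         "pct_selected": 100.0 * count / n_folds})
    return pd.DataFrame(rows)


def training_size_sweep(dataset: StudyDataset, model: ModelSpec,
                        scenario: ScenarioSpec, fractions,
                        inner_folds: int = 10, seed: int = 0,
                        min_test_rows: int = 20) -> pd.DataFrame:
    """Test-set RMSE after tuning on a shrinking training split.

    One seeded random split per fraction: the first ``f * n`` shuffled rows
    train (with grid-search tuning inside), the remainder tests.
    """
    X, y = _design(dataset, scenario)
    n = len(y)
    rows = []
    for f in fractions:
        if not (0.0 < f < 1.0):
            raise SweepError(f"fraction {f} outside (0, 1)")
        n_train = int(round(f * n))
        if n - n_train < min_test_rows:
            raise SweepError(
                f"fraction {f} leaves only {n - n_train} test rows"
            )
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        params, _ = _grid_search(model, X[tr], y[tr], inner_folds,
                                 seed=seed + 17)
        est = model.make_estimator(params, seed=seed + 18)
        est.fit(X[tr], y[tr])
        rmse = float(np.sqrt(np.mean((est.predict(X[te]) - y[te]) ** 2)))
        rows.append({"fraction": f, "n_train": n_train, "rmse": rmse,
                     **{f"hp_{k}": v for k, v in params.items()}})
    return pd.DataFrame(rows)


def fit_full_and_predict_external(train_dataset: StudyDataset,
                                  model: ModelSpec, scenario: ScenarioSpec,
                                  external: pd.DataFrame,
                                  inner_folds: int = 10,
                                  seed: int = 0) -> np.ndarray:
    """Tune on the full training table, refit, predict the external rows."""
    X, y = _design(train_dataset, scenario)
    X_ext, _ = _design(external, scenario, need_target=False)
    params, _ = _grid_search(model, X, y, inner_folds, seed=seed + 31)
    est = model.make_estimator(params, seed=seed + 32)
    est.fit(X, y)
    return est.predict(X_ext)
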