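"""Agreement statistics for predicted vs reference values.

Covers the study's full reporting battery: least-squares slope/intercept of
predicted on reference, Pearson r with two-sided p, per-fold RMSE / nRMSE /
MAE (mean +/- sample SD over folds; nRMSE normalises by the fold's reference
range), Bland-Altman bias and 1.96-SD limits of agreement, absolute-error
threshold compliance, impurity feature importances averaged over folds, OLS
coefficient t-tests, and pairwise correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidParameterError, PreconditionError, SingularDesignError
from .regression import CVRunResult

__all__ = [
    "MetricsReport",
    "BlandAltman",
    "COMPLIANCE_THRESHOLDS",
    "regression_report",
    "bland_altman",
    "threshold_compliance",
    "feature_importance_summary",
    "ols_coefficient_tests",
    "correlation_matrix",
]

#: Per-target absolute-error compliance thresholds (ascending).
COMPLIANCE_THRESHOLDS: dict[str, tuple[float, ...]] = {
    "aSBP": (5.0,),            # mmHg
    "CO": (0.3, 0.5),          # L/min
    "E_es": (0.05, 0.20),      # mmHg/mL
}


@dataclass(frozen=True)
class MetricsReport:
    """Agreement summary for one prediction set."""

    slope: float
    intercept: float
    r: float
    r2: float
    p_value: float
    rmse: float
    rmse_sd: float
    nrmse_pct: float
    nrmse_pct_sd: float
    mae: float
    mae_sd: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd: float


def _fold_stats(pred, ref, fold_ids):
    rmse, nrmse, mae = [], [], []
    for k in np.unique(fold_ids):
        m = fold_ids == k
        resid = pred[m] - ref[m]
        fold_rmse = float(np.sqrt(np.mean(resid ** 2)))
        rng = float(ref[m].max() - ref[m].min())
        rmse.append(fold_rmse)
        nrmse.append(100.0 * fold_rmse / rng if rng > 0 else np.nan)
        mae.append(float(np.mean(np.abs(resid))))
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return ((float(np.mean(rmse)), sd(rmse)),
            (float(np.nanmean(nrmse)), sd(nrmse)),
            (float(np.mean(mae)), sd(mae)))


def regression_report(pred, ref, fold_ids=None) -> MetricsReport:
    """Full agreement report; with no folds given, one pooled 'fold'."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.size < 3:
        raise PreconditionError("need equal-length vectors with >= 3 points")
    if np.ptp(ref) == 0:
        raise InvalidParameterError("reference is constant; correlation undefined")
    fold_ids = (np.zeros(pred.size, dtype=int) if fold_ids is None
                else np.asarray(fold_ids))
    slope, intercept = np.polyfit(ref, pred, 1)
    r, p = stats.pearsonr(pred, ref)
    (rmse, rmse_sd), (nrmse, nrmse_sd), (mae, mae_sd) = _fold_stats(
        pred, ref, fold_ids
    )
    return MetricsReport(
        slope=float(slope), intercept=float(intercept), r=float(r),
        r2=float(r) ** 2, p_value=float(p), rmse=rmse, rmse_sd=rmse_sd,
        nrmse_pct=nrmse, nrmse_pct_sd=nrmse_sd, mae=mae, mae_sd=mae_sd,
        n=int(pred.size),
    )


def bland_altman(pred, ref) -> BlandAltman:
    """Bias and 1.96-sample-SD limits of agreement of pred - ref."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.size < 2:
        raise PreconditionError("need equal-length vectors with >= 2 points")
    d = pred - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd, sd=sd)


def threshold_compliance(pred, ref, thresholds) -> dict[float, float]:
    """Percent of |pred - ref| strictly below each threshold."""
    err = np.abs(np.asarray(pred, dtype=float) - np.asarray(ref, dtype=float))
    return {float(tau): float(100.0 * np.mean(err < tau)) for tau in thresholds}


def feature_importance_summary(run: CVRunResult,
                               dataset) -> pd.DataFrame:
    """Mean Random-Forest impurity importance per feature over outer folds.

    Refits the fold-selected Random Forest on each outer-training set (the
    out-of-fold protocol's fitted models) and averages the normalised
    impurity importances; rows are sorted descending.
    """
    if run.model.family != "random_forest":
        raise InvalidParameterError(
            "feature importances require a random_forest run"
        )
    from .regression import _design  # shared design-matrix helper

    X, y = _design(dataset, run.scenario)
    imps = []
    for k, params in enumerate(run.fold_params):
        tr = run.fold_ids != k
        est = run.model.make_estimator(params, seed=run.cv.seed + 2000 + k)
        est.fit(X[tr], y[tr])
        imps.append(est.feature_importances_)
    mean_imp = np.mean(imps, axis=0)
    out = pd.DataFrame({
        "feature": list(run.scenario.features),
        "importance": mean_imp,
    }).sort_values("importance", ascending=False).reset_index(drop=True)
    return out


def ols_coefficient_tests(features: pd.DataFrame, target) -> pd.DataFrame:
    """OLS with intercept; per-coefficient estimate, t and two-sided p."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise PreconditionError("need n > p + 1 observations")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    names = ["intercept"] + list(
        features.columns if isinstance(features, pd.DataFrame)
        else [f"x{i}" for i in range(p)]
    )
    return pd.DataFrame({
        "coefficient": names,
        "estimate": fit.params,
        "t": fit.tvalues,
        "p": fit.pvalues,
    }).reset_index(drop=True)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations; constant columns flagged as NaN."""
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        raise PreconditionError("need at least two numeric columns")
    return numeric.corr(method="pearson")
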