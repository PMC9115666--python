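"""Feature-to-concentration regression: multivariable linear regression,
partial least squares on mean spectra, overall-significance F-test and
RMSE / R-squared evaluation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .core import DegenerateDataError, FeatureVector, InvalidParameterError

__all__ = [
    "RegressionFit",
    "PredictionResult",
    "fit_mlr",
    "f_test_overall",
    "fit_plsr",
    "predict",
    "evaluate",
]


@dataclass
class RegressionFit:
    kind: str  # "mlr" | "plsr"
    coefficients: np.ndarray
    intercept: float
    n_components: Optional[int] = None
    model: object = None
    rmse: float = np.nan
    r2: float = np.nan
    f_statistic: float = np.nan
    p_value: float = np.nan
    diagnostics: dict = field(default_factory=dict)


@dataclass
class PredictionResult:
    measured: np.ndarray
    predicted: np.ndarray

    def __post_init__(self):
        self.measured = np.asarray(self.measured, dtype=float).ravel()
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        if self.measured.shape != self.predicted.shape:
            raise InvalidParameterError("measured/predicted length mismatch")

    @property
    def residuals(self) -> np.ndarray:
        return self.measured - self.predicted


def _as_feature_matrix(features: Union[np.ndarray, Sequence[FeatureVector]]
                       ) -> np.ndarray:
    if len(features) and isinstance(features[0], FeatureVector):
        return np.vstack([f.values for f in features])
    return np.atleast_2d(np.asarray(features, dtype=float))


def fit_mlr(features, y) -> RegressionFit:
    """Ordinary least squares with intercept on per-sample features."""
    a = _as_feature_matrix(features)
    y = np.asarray(y, dtype=float).ravel()
    n, m = a.shape
    if y.shape[0] != n:
        raise InvalidParameterError("feature/response length mismatch")
    if n <= m + 1:
        raise InvalidParameterError(f"need N > M + 1 samples (N={n}, M={m})")
    design = np.column_stack([np.ones(n), a])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise DegenerateDataError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            f"collinear feature columns: {bad}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    y_hat = design @ beta
    pred = PredictionResult(measured=y, predicted=y_hat)
    rmse, r2 = evaluate(pred)
    f_stat, p_val = f_test_overall(pred, n_predictors=m)
    return RegressionFit(kind="mlr", coefficients=beta[1:], intercept=float(beta[0]),
                         rmse=rmse, r2=r2, f_statistic=f_stat, p_value=p_val)


def _collinear_columns(design: np.ndarray):
    """Columns (0 = intercept) that are linear combinations of earlier ones."""
    bad = []
    for j in range(1, design.shape[1]):
        if np.linalg.matrix_rank(design[:, : j + 1]) <= np.linalg.matrix_rank(
                design[:, :j]):
            bad.append(j - 1)
    return bad


def f_test_overall(pred: PredictionResult, n_predictors: int
                   ) -> Tuple[float, float]:
    """F-test of overall significance against the intercept-only model.

    F = (SSR / p) / (SSE / (N - p - 1)) with the p-value from the
    F(p, N - p - 1) distribution.
    """
    y, y_hat = pred.measured, pred.predicted
    n = y.size
    p = int(n_predictors)
    if p < 1:
        raise InvalidParameterError("need at least one predictor")
    if n <= p + 1:
        raise InvalidParameterError("need N > p + 1 observations")
    ssr = float(np.sum((y_hat - y.mean()) ** 2))
    sse = float(np.sum((y - y_hat) ** 2))
    dfe = n - p - 1
    if sse <= 1e-300:
        warnings.warn("perfect fit: SSE is zero, reporting p-value 0")
        return np.inf, 0.0
    f_stat = (ssr / p) / (sse / dfe)
    p_val = float(stats.f.sf(f_stat, p, dfe))
    return float(f_stat), p_val


def fit_plsr(mean_spectra: np.ndarray, y, n_components: Optional[int] = None,
             max_components: int = 10, cv_folds: int = 3,
             seed: int = 0) -> RegressionFit:
    """Partial least squares regression on per-sample mean spectra.

    When n_components is None it is chosen from 1..max_components by inner
    cross-validated RMSE (standard chemometrics practice; logged in the
    diagnostics).
    """
    x = np.asarray(mean_spectra, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, b = x.shape
    if y.shape[0] != n:
        raise InvalidParameterError("spectra/response length mismatch")
    cap = min(n - 1, b)
    if n_components is not None:
        if not 1 <= n_components <= cap:
            raise InvalidParameterError(
                f"n_components must be in [1, {cap}], got {n_components}"
            )
        chosen = n_components
        diag = {"selection": "fixed"}
    else:
        chosen, cv_table = _select_components(x, y, min(max_components, cap),
                                              cv_folds, seed)
        diag = {"selection": "inner-cv", "cv_rmse": cv_table}
    model = PLSRegression(n_components=chosen, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    y_hat = model.predict(x).ravel()
    pred = PredictionResult(measured=y, predicted=y_hat)
    rmse, r2 = evaluate(pred)
    f_stat, p_val = f_test_overall(pred, n_predictors=chosen)
    return RegressionFit(kind="plsr", coefficients=model.coef_.ravel(),
                         intercept=float(model.intercept_.ravel()[0]),
                         n_components=chosen, model=model, rmse=rmse, r2=r2,
                         f_statistic=f_stat, p_value=p_val, diagnostics=diag)


def _select_components(x, y, max_components, cv_folds, seed):
    folds = min(cv_folds, x.shape[0])
    table = {}
    for k in range(1, max_components + 1):
        errors = []
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        for train, test in kf.split(x):
            if k > min(len(train) - 1, x.shape[1]):
                errors = None
                break
            model = PLSRegression(n_components=k, scale=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x[train], y[train])
            pred = model.predict(x[test]).ravel()
            errors.append(np.mean((y[test] - pred) ** 2))
        if errors is None:
            break
        table[k] = float(np.sqrt(np.mean(errors)))
    chosen = min(table, key=table.get)
    return chosen, table


def predict(fit: RegressionFit, features_or_spectra) -> np.ndarray:
    """Apply a fitted model to new features (MLR) or mean spectra (PLSR)."""
    if fit.kind == "mlr":
        a = _as_feature_matrix(features_or_spectra)
        return a @ fit.coefficients + fit.intercept
    if fit.kind == "plsr":
        x = np.atleast_2d(np.asarray(features_or_spectra, dtype=float))
        return fit.model.predict(x).ravel()
    raise InvalidParameterError(f"unknown fit kind '{fit.kind}'")


def evaluate(pred: PredictionResult) -> Tuple[float, float]:
    """(RMSE, R^2); R^2 uses the total sum of squares about mean(measured)."""
    y, y_hat = pred.measured, pred.predicted
    if y.size < 2:
        raise InvalidParameterError("need at least 2 observations")
    res = y - y_hat
    rmse = float(np.sqrt(np.mean(res ** 2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 1e-300:
        warnings.warn("zero variance in measured values: R^2 undefined")
        return rmse, np.nan
    r2 = 1.0 - float(np.sum(res ** 2)) / sst
    return rmse, r2
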