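"""Minimum-norm OLS estimation, hat matrix, and fit metrics.

The design stacks one half-constant column per predictor, so for p >= 2 the
Gram matrix X'X is singular.  Every occurrence of (X'X)^{-1} is therefore
computed with the Moore-Penrose pseudoinverse, which returns the minimum-norm
least-squares solution (splitting the shared intercept equally across the
collinear columns) and reduces to the ordinary inverse on full-rank designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .basis import DesignMatrix
from .exceptions import InputDataError, SaturatedModelError

__all__ = ["FitMetrics", "FittedModel", "fit_ols", "hat_matrix", "fit_metrics"]


@dataclass(frozen=True)
class FitMetrics:
    """Goodness-of-fit summary: R^2, MSE (Q/n), MAE, RMSE, MAPE."""

    r2: float
    mse: float
    mae: float
    rmse: float
    mape: float  # nan when some y_i == 0

    def as_dict(self) -> dict[str, float]:
        return {
            "R2": self.r2,
            "MSE": self.mse,
            "MAE": self.mae,
            "RMSE": self.rmse,
            "MAPE": self.mape,
        }


@dataclass
class FittedModel:
    """Result of a minimum-norm least-squares fit of y on a Fourier design."""

    design: DesignMatrix
    y: np.ndarray
    delta_hat: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    df_model: int
    df_resid: int
    sigma2_mle: float  # Q / n
    sigma2_resid: float  # Q / r
    gram_pinv: np.ndarray  # (X'X)^+, shared by all downstream formulas
    metrics: FitMetrics

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def L(self) -> int:
        return self.delta_hat.size


def _compute_metrics(y: np.ndarray, residuals: np.ndarray, rss: float) -> FitMetrics:
    n = y.size
    mse = rss / n
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(residuals)))
    if np.any(y == 0.0):
        warnings.warn(
            "MAPE undefined: response contains zeros; reporting nan", stacklevel=3
        )
        mape = float("nan")
    else:
        mape = float(np.mean(np.abs(residuals / y)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        r2 = 1.0 if rss <= 1e-30 else float("nan")
        if np.isnan(r2):
            warnings.warn("R2 undefined: response is constant", stacklevel=3)
    else:
        r2 = 1.0 - rss / sst
    return FitMetrics(r2=r2, mse=float(mse), mae=mae, rmse=rmse, mape=mape)


def fit_ols(design: DesignMatrix, y: np.ndarray) -> FittedModel:
    """Fit y = X delta + eps by least squares.

    Among all minimizers of ||y - X delta||^2 the minimum-norm one is
    returned; on full-rank designs this is the unique OLS solution.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != design.n:
        raise InputDataError(
            f"response length {y.size} does not match design rows {design.n}"
        )
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        raise InputDataError(f"non-finite response value at row {bad[0]}")
    if y.size <= design.rank:
        raise SaturatedModelError("saturated model: no residual degrees of freedom")

    X = design.values
    gram_pinv = np.linalg.pinv(X.T @ X)
    delta_hat = gram_pinv @ (X.T @ y)
    fitted = X @ delta_hat
    residuals = y - fitted
    rss = float(residuals @ residuals)
    df_model = design.rank
    df_resid = y.size - df_model

    return FittedModel(
        design=design,
        y=y,
        delta_hat=delta_hat,
        fitted=fitted,
        residuals=residuals,
        rss=rss,
        df_model=df_model,
        df_resid=df_resid,
        sigma2_mle=rss / y.size,
        sigma2_resid=rss / df_resid,
        gram_pinv=gram_pinv,
        metrics=_compute_metrics(y, residuals, rss),
    )


def hat_matrix(design: DesignMatrix) -> np.ndarray:
    """The n x n orthogonal projector U = X (X'X)^+ X' onto the column space of X."""
    X = design.values
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def fit_metrics(model: FittedModel, y: np.ndarray | None = None) -> FitMetrics:
    """Recompute the goodness-of-fit metrics of ``model`` against ``y``."""
    if y is None:
        y = model.y
    y = np.asarray(y, dtype=float).ravel()
    residuals = y - model.fitted
    rss = float(residuals @ residuals)
    return _compute_metrics(y, residuals, rss)
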