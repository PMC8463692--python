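"""Multivariate multiple linear regression (MLR) by ordinary least squares.

One linear model maps p LFP-feature predictors to m spiking responses:

    Y = X B + E,        B_hat = (X^T X)^{-1} X^T Y

with a constant column prepended to X for the intercepts.  The solver
uses a least-squares factorization (numpy ``lstsq``) rather than the
explicit inverse; equivalence to the normal equations on
well-conditioned inputs is a test property, not the implementation.
Rank-deficient designs (e.g. duplicated channels in a random subset)
yield the minimum-norm solution with a warning instead of failing.
No regularization anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureColumn, FeatureMatrix, TargetColumn, TargetMatrix


@dataclass
class MLRModel:
    """Fitted MLR: intercept vector (m,) and coefficient matrix (p, m)."""

    intercepts: np.ndarray
    coefficients: np.ndarray
    feature_columns: tuple[FeatureColumn, ...] | None = None
    target_columns: tuple[TargetColumn, ...] | None = None
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 2:
            raise ValueError("coefficients must be (p, m)")
        if self.intercepts.shape != (self.coefficients.shape[1],):
            raise ValueError("intercept length must match coefficient columns")
        if not (np.isfinite(self.intercepts).all() and np.isfinite(self.coefficients).all()):
            raise ValueError("non-finite model parameters")

    @property
    def p(self) -> int:
        return self.coefficients.shape[0]

    @property
    def m(self) -> int:
        return self.coefficients.shape[1]


def _coerce_x(X) -> tuple[np.ndarray, tuple[FeatureColumn, ...] | None]:
    if isinstance(X, FeatureMatrix):
        return X.values, X.columns
    return np.atleast_2d(np.asarray(X, dtype=float)), None


def _coerce_y(Y) -> tuple[np.ndarray, tuple[TargetColumn, ...] | None]:
    if isinstance(Y, TargetMatrix):
        return Y.values, Y.columns
    arr = np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, None


def fit_mlr(X, Y, store_residuals: bool = False) -> MLRModel:
    """Fit the OLS solution of Y = [1 X] B.

    Parameters
    ----------
    X, Y
        Row-aligned predictors (n x p) and responses (n x m); plain
        arrays or Feature/TargetMatrix.  Requires n > p + 1.
    store_residuals
        Keep the n x m training residual matrix on the model.
    """
    Xv, xcols = _coerce_x(X)
    Yv, ycols = _coerce_y(Y)
    n, p = Xv.shape
    if Yv.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 rows (got n={n}, p={p})")
    design = np.column_stack([np.ones(n), Xv])
    coef, _, rank, _ = np.linalg.lstsq(design, Yv, rcond=None)
    if rank < p + 1:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {p + 1}); "
            "returning the minimum-norm solution",
            RuntimeWarning,
            stacklevel=2,
        )
    residuals = Yv - design @ coef if store_residuals else None
    return MLRModel(
        intercepts=coef[0],
        coefficients=coef[1:],
        feature_columns=xcols,
        target_columns=ycols,
        residuals=residuals,
    )


def predict_mlr(model: MLRModel, X) -> np.ndarray:
    """Predict Y_hat = 1 b0^T + X B for new predictor rows."""
    Xv, xcols = _coerce_x(X)
    if (
        xcols is not None
        and model.feature_columns is not None
        and xcols != model.feature_columns
    ):
        raise ValueError("feature descriptors do not match the fitted model")
    if Xv.shape[1] != model.p:
        raise ValueError(f"X has {Xv.shape[1]} columns, model expects {model.p}")
    return model.intercepts + Xv @ model.coefficients
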