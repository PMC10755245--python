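"""Shared numerical helpers: design matrices, least-squares residualization."""

from __future__ import annotations

import numpy as np
import pandas as pd


def as_2d(covariates) -> tuple[np.ndarray, list[str]]:
    """Coerce covariates (None, vector, matrix, DataFrame) to (n x k) float array
    plus column names."""
    if covariates is None:
        return np.empty((0, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    names = [f"cov{i}" for i in range(arr.shape[1])]
    return arr, names


def design_matrix(n: int, covariates) -> tuple[np.ndarray, list[str]]:
    """[intercept | covariates] design; raises naming collinear columns."""
    cov, names = as_2d(covariates)
    if cov.size:
        if cov.shape[0] != n:
            raise ValueError("covariate rows do not match data length")
        X = np.column_stack([np.ones(n), cov])
    else:
        X = np.ones((n, 1))
    names = ["intercept"] + names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = collinear_columns(X, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, names


def collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns that add no rank when appended left-to-right (QR sweep)."""
    bad, kept = [], np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            kept = cand
        else:
            bad.append(names[j])
    return bad


def residualize_on(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residual of y (vector or matrix of columns) on X."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def percentage(numerator: float, denominator: float, ndigits: int | None = None) -> float:
    """100 * numerator / denominator, optionally rounded to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    pct = 100.0 * numerator / denominator
    return round(pct, ndigits) if ndigits is not None else pct
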