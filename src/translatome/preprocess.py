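"""RMA-style signal preprocessing.

Raw array signals are processed the way the Robust Multi-array Average
route does: log2 transformation, quantile normalization across arrays,
and (for probe-level data) Tukey median-polish summarization of probes
into one per-gene value per array.  The full MAS5 Wilcoxon detection
call and the RMA convolution background model are deliberately not
reimplemented: detection calls are simple log2-signal thresholds and
background correction is a non-negative shift, because the downstream
translation-state statistics are the point of the package, not the
array black boxes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import DetectionCallMatrix, SignalMatrix

__all__ = ["QuantileNormalizer", "quantile_normalize", "median_polish",
           "median_polish_summarize", "detection_calls",
           "background_shift"]


def _map_to_reference(col: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace ``col`` by the reference order statistics, rank for rank.

    Tied values receive the mean of the reference values at the tied
    positions, which keeps the mapping deterministic and symmetric.
    """
    order = np.argsort(col, kind="mergesort")
    out = np.empty(col.shape, dtype=float)
    out[order] = reference
    sorted_vals = col[order]
    # average the reference over runs of equal input values
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [col.size]))
    for a, b in zip(starts, stops):
        if b - a > 1:
            out[order[a:b]] = reference[a:b].mean()
    return out


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization across arrays.

    ``fit`` learns the reference distribution (the across-array mean of
    each order statistic); ``transform`` maps every array onto it, rank
    for rank.  After ``fit_transform`` on a matrix, every array has the
    identical sorted value vector and within-array ranks are preserved.

    Follows the scikit-learn transformer protocol with arrays as samples
    (rows) and genes as features (columns).

    Parameters
    ----------
    na_policy : {"raise", "drop"}
        ``raise`` (default) rejects matrices with missing values;
        ``drop`` removes genes with any missing value before fitting and
        transforming.
    """

    def __init__(self, na_policy: str = "raise"):
        self.na_policy = na_policy

    def _check(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D arrays x genes matrix")
        if np.isnan(X).any():
            if self.na_policy == "raise":
                raise ValueError("missing values present; pass "
                                 "na_policy='drop' or impute first")
            if self.na_policy != "drop":
                raise ValueError(f"unknown na_policy {self.na_policy!r}")
        return X

    def fit(self, X, y=None):
        X = self._check(X)
        if X.shape[0] < 2:
            raise ValueError("quantile normalization needs >=2 arrays")
        keep = ~np.isnan(X).any(axis=0)
        self.kept_mask_ = keep
        self.reference_ = np.sort(X[:, keep], axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = self._check(X)
        keep = self.kept_mask_
        out = np.full(X.shape, np.nan)
        for i in range(X.shape[0]):
            out[i, keep] = _map_to_reference(X[i, keep], self.reference_)
        return out


def quantile_normalize(matrix, na_policy: str = "raise"):
    """Quantile-normalize a genes x arrays matrix.

    Accepts and returns a :class:`SignalMatrix` or a plain DataFrame /
    ndarray (genes in rows, arrays in columns).  Genes dropped under
    ``na_policy='drop'`` come back as missing values.
    """
    if isinstance(matrix, SignalMatrix):
        norm = quantile_normalize(matrix.values, na_policy=na_policy)
        return matrix.with_values(norm)
    if isinstance(matrix, pd.DataFrame):
        arr = quantile_normalize(matrix.to_numpy(dtype=float),
                                 na_policy=na_policy)
        return pd.DataFrame(arr, index=matrix.index, columns=matrix.columns)
    X = np.asarray(matrix, dtype=float).T  # arrays become rows
    return QuantileNormalizer(na_policy=na_policy).fit_transform(X).T


def background_shift(matrix: pd.DataFrame,
                     quantile: float = 0.0) -> pd.DataFrame:
    """Non-negative background shift: subtract each array's ``quantile``
    value and clip at zero.  ``quantile=0`` subtracts the array minimum."""
    q = matrix.quantile(quantile, axis=0)
    return (matrix - q).clip(lower=0.0)


def median_polish(matrix, max_iter: int = 10, tol: float = 1e-6):
    """Tukey median polish of a 2-D matrix.

    Alternately sweeps out row and column medians until the largest
    absolute row/column median falls below ``tol`` or ``max_iter``
    passes have run.

    Returns
    -------
    overall : float
    row_effects : ndarray, shape (n_rows,)
    col_effects : ndarray, shape (n_cols,)
    residuals : ndarray, same shape as the input
    """
    resid = np.array(matrix, dtype=float, copy=True)
    if resid.ndim != 2:
        raise ValueError("median polish expects a 2-D matrix")
    nrow, ncol = resid.shape
    overall = 0.0
    row_eff = np.zeros(nrow)
    col_eff = np.zeros(ncol)
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row_eff += rmed
        cmed_of_row = np.median(row_eff)
        row_eff -= cmed_of_row
        overall += cmed_of_row

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col_eff += cmed
        rmed_of_col = np.median(col_eff)
        col_eff -= rmed_of_col
        overall += rmed_of_col

        if max(np.abs(np.median(resid, axis=1)).max(initial=0.0),
               np.abs(np.median(resid, axis=0)).max(initial=0.0)) < tol:
            break
    return overall, row_eff, col_eff, resid


def median_polish_summarize(probe_matrix,
                            max_iter: int = 10,
                            tol: float = 1e-6) -> np.ndarray:
    """Summarize a probes x arrays log2 matrix into one value per array.

    Returns overall + column (array) effects of the median polish, the
    RMA summarization convention.  A single-probe gene returns that
    probe's values unchanged.
    """
    probe_matrix = np.asarray(probe_matrix, dtype=float)
    if probe_matrix.ndim == 1:
        probe_matrix = probe_matrix[None, :]
    if probe_matrix.shape[0] == 0:
        raise ValueError("gene has no probes")
    if probe_matrix.shape[0] == 1:
        return probe_matrix[0].copy()
    overall, _, col_eff, _ = median_polish(probe_matrix, max_iter=max_iter,
                                           tol=tol)
    return overall + col_eff


def detection_calls(matrix, absent_threshold: float = 6.0,
                    marginal_threshold: float = 7.0):
    """Threshold-based Present/Marginal/Absent calls on log2 signals.

    call = A if log2 signal < ``absent_threshold``, M if in
    [absent, marginal), else P.  Missing signals are called A.
    """
    if absent_threshold > marginal_threshold:
        raise ValueError("absent_threshold must be <= marginal_threshold")
    if isinstance(matrix, SignalMatrix):
        if not matrix.log2:
            raise ValueError("detection thresholds are on the log2 scale; "
                             "log2-transform the signals first")
        df = matrix.values
    else:
        df = pd.DataFrame(matrix)
    arr = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(arr) | (arr < absent_threshold), "A",
                     np.where(arr < marginal_threshold, "M", "P"))
    return DetectionCallMatrix(pd.DataFrame(calls, index=df.index,
                                            columns=df.columns))
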