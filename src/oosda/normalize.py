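"""Cyclic LOESS normalization of log2 spectra.

Suppresses intensity-dependent distortions (decay over the injection
sequence, ion suppression) by iteratively flattening the MA-trend between
every pair of samples: for columns i and j the log-ratio M = x_i - x_j is
regressed on the average A = (x_i + x_j)/2 with a local linear smoother and
half of the fitted trend is subtracted from one column and added to the
other.  One iteration sweeps all unordered pairs in lexicographic order.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .table import FeatureTable, ValidationError

__all__ = ["CyclicLoessNormalizer", "cyclic_loess", "cyclic_loess_matrix"]

#: a local regression needs a handful of points to be meaningful
_MIN_SHARED = 10


def _loess_fit(A: np.ndarray, M: np.ndarray, span: float, degree: int) -> np.ndarray:
    """Fitted LOESS trend of M on A, evaluated at the data points."""
    lo, hi = float(A.min()), float(A.max())
    delta = 0.01 * (hi - lo)
    return lowess(
        M, A, frac=span, it=0, delta=delta, return_sorted=False
    )


def cyclic_loess_matrix(
    X: np.ndarray, span: float = 0.7, iterations: int = 3
) -> np.ndarray:
    """Normalize the columns of a log2 matrix (features x samples) in place
    of a copy; NaN cells are left untouched and excluded from every fit."""
    X = np.array(X, dtype=float)
    n = X.shape[1]
    for _ in range(iterations):
        for i in range(n - 1):
            for j in range(i + 1, n):
                xi, xj = X[:, i], X[:, j]
                shared = ~np.isnan(xi) & ~np.isnan(xj)
                if shared.sum() < _MIN_SHARED:
                    warnings.warn(
                        f"columns {i} and {j} share fewer than {_MIN_SHARED} "
                        "features; pair skipped",
                        stacklevel=2,
                    )
                    continue
                A = (xi[shared] + xj[shared]) / 2.0
                M = xi[shared] - xj[shared]
                if A.max() == A.min():
                    f = np.full(M.shape, M.mean())
                else:
                    f = _loess_fit(A, M, span, 1)
                xi[shared] -= f / 2.0
                xj[shared] += f / 2.0
    return X


class CyclicLoessNormalizer(TransformerMixin, BaseEstimator):
    """Pairwise cyclic LOESS normalizer (scikit-learn interface).

    Follows the sklearn convention that rows are samples and columns are
    features.  The normalization is joint over the samples handed to
    ``transform`` — there is no training state, so ``fit`` only validates.

    Parameters
    ----------
    span : float, default 0.7
        LOESS smoothing span (fraction of points in each local fit).
    iterations : int, default 3
        Number of full sweeps over all sample pairs.
    """

    def __init__(self, span: float = 0.7, iterations: int = 3):
        self.span = span
        self.iterations = iterations

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least two samples")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return cyclic_loess_matrix(X.T, self.span, self.iterations).T


def cyclic_loess(
    table: FeatureTable, span: float = 0.7, iterations: int = 3
) -> FeatureTable:
    """Cyclic LOESS normalization of a log2-scale feature table."""
    if table.scale != "log2":
        raise ValidationError("cyclic LOESS is defined on log2 intensities")
    if table.n_samples < 2:
        raise ValidationError("need at least two samples to normalize")
    out = table.copy()
    out.values = cyclic_loess_matrix(table.values, span, iterations)
    return out
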