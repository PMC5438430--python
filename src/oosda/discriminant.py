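"""Optimal orthonormal system for discriminant analysis (OOS-DA).

OOS-DA generalizes Fisher's linear discriminant to a sequence of mutually
orthonormal directions.  The first direction maximizes the Fisher ratio

    J(w) = (w' S_b w) / (w' S_w w)

over unit vectors, where S_b and S_w are the between- and within-class
scatter matrices.  Each subsequent direction maximizes the same ratio
subject to orthonormality with all previous directions.  The constrained
problems are solved exactly by projecting both scatters onto an orthonormal
basis of the orthogonal complement of the directions found so far and
taking the leading generalized eigenvector there.

Unlike PLS-DA, which inherits its criterion from regression, this
construction is rooted directly in pattern classification: for a single
axis and two classes it reduces to the classical Fisher discriminant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["ScatterPair", "compute_scatter", "OOSDA", "fit_oosda"]


@dataclass
class ScatterPair:
    """Between- and within-class scatter matrices of a labeled dataset."""

    S_b: np.ndarray
    S_w: np.ndarray
    class_sizes: list[int]

    @property
    def total(self) -> np.ndarray:
        return self.S_b + self.S_w


def compute_scatter(
    X: np.ndarray, labels: np.ndarray, weighted: bool = True
) -> ScatterPair:
    """Scatter matrices of samples-in-rows data ``X`` (N x p).

    S_w sums squared deviations of each sample from its class mean;
    S_b sums (class-size-weighted by default) squared deviations of class
    means from the grand sample mean.  No 1/N normalization is applied —
    Fisher ratios are invariant to it.  S_b + S_w equals the total scatter
    of the centered data when ``weighted`` is True.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or len(labels) != X.shape[0]:
        raise ValueError("X must be N x p with one label per row")
    if np.isnan(X).any():
        raise ValueError("scatter matrices require complete data (impute first)")
    p = X.shape[1]
    classes, inverse = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        warnings.warn("single class: S_b is zero", stacklevel=2)
    grand = X.mean(axis=0)
    S_w = np.zeros((p, p))
    S_b = np.zeros((p, p))
    sizes = []
    for k in range(len(classes)):
        Xk = X[inverse == k]
        sizes.append(len(Xk))
        mk = Xk.mean(axis=0)
        D = Xk - mk
        S_w += D.T @ D
        diff = (mk - grand)[:, None]
        w = len(Xk) if weighted else 1.0
        S_b += w * (diff @ diff.T)
    return ScatterPair(S_b, S_w, sizes)


def _orth_complement(W: np.ndarray, p: int) -> np.ndarray:
    """Orthonormal basis (p x (p-m)) of the complement of span(W)."""
    if W.shape[1] == 0:
        return np.eye(p)
    Q, _ = np.linalg.qr(np.hstack([W, np.eye(p)]))
    # first m columns of Q span W; the rest span the complement
    return Q[:, W.shape[1]:p]


def _leading_gev(S_b: np.ndarray, S_w: np.ndarray, jitter_rel: float = 1e-10):
    """Leading generalized eigenpair of (S_b, S_w), with a trace-scaled
    ridge on S_w when it is numerically singular (logged via warning)."""
    p = S_b.shape[0]
    Sw = (S_w + S_w.T) / 2.0
    Sb = (S_b + S_b.T) / 2.0
    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    except scipy.linalg.LinAlgError:
        jitter = jitter_rel * np.trace(Sw) / max(p, 1)
        if jitter <= 0:
            jitter = jitter_rel
        warnings.warn(
            f"within-class scatter singular; adding ridge {jitter:.3e}",
            stacklevel=2,
        )
        evals, evecs = scipy.linalg.eigh(Sb, Sw + jitter * np.eye(p))
    return float(evals[-1]), evecs[:, -1]


class OOSDA(TransformerMixin, BaseEstimator):
    """Sequential orthonormal Fisher-discriminant decomposition.

    Fits ``n_components`` mutually orthonormal directions, each maximizing
    the between/within scatter ratio within the orthogonal complement of
    its predecessors.  Follows the scikit-learn estimator contract: rows of
    ``X`` are samples.

    Parameters
    ----------
    n_components : int
        Number of discriminant axes to extract.
    scatter_weighting : {"size", "unweighted"}, default "size"
        Whether between-class scatter weights class means by class size.
    cond_max : float, default 1e8
        Condition-number bound above which the within-class scatter is
        declared numerically singular.

    Attributes
    ----------
    components_ : ndarray (n_components, n_features)
        The orthonormal loading vectors, one per row (columns of the
        loading matrix P in the latent model x ~ P t).
    criterion_values_ : ndarray (n_components,)
        Fisher ratio attained by each axis within its feasible subspace.
    classes_ : ndarray
        Sorted class labels seen during fit.
    """

    def __init__(
        self,
        n_components: int = 3,
        scatter_weighting: str = "size",
        cond_max: float = 1e8,
    ):
        self.n_components = n_components
        self.scatter_weighting = scatter_weighting
        self.cond_max = cond_max

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if len(y) != X.shape[0]:
            raise ValueError("one label per sample required")
        p = X.shape[1]
        if not 1 <= self.n_components <= p:
            raise ValueError(
                f"n_components must be in [1, {p}], got {self.n_components}"
            )
        scatter = compute_scatter(
            X, y, weighted=(self.scatter_weighting == "size")
        )
        if not np.any(scatter.S_b):
            raise ValueError("degenerate class structure: zero between-class scatter")
        sw_eigs = np.linalg.eigvalsh((scatter.S_w + scatter.S_w.T) / 2.0)
        if sw_eigs[-1] <= 0 or sw_eigs[-1] / max(sw_eigs[0], 1e-300) > self.cond_max:
            raise ValueError(
                "within-class scatter is numerically singular "
                f"(condition number > {self.cond_max:.0e}); increase the "
                "PCA pre-compression parameter k"
            )
        W = np.empty((p, 0))
        crit = []
        for _ in range(self.n_components):
            B = _orth_complement(W, p)
            lam, v = _leading_gev(B.T @ scatter.S_b @ B, B.T @ scatter.S_w @ B)
            w = B @ v
            w /= np.linalg.norm(w)
            # sign convention: largest-magnitude entry positive
            if w[np.argmax(np.abs(w))] < 0:
                w = -w
            W = np.hstack([W, w[:, None]])
            crit.append(lam)
        self.components_ = W.T
        self.criterion_values_ = np.asarray(crit)
        self.classes_ = np.unique(y)
        self.scatter_ = scatter
        self.n_features_in_ = p
        return self

    def transform(self, X):
        """Latent scores t = W' x for each sample (row) of X."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[-1]} features, expected {self.n_features_in_}"
            )
        return X @ self.components_.T

    def remove(self, X, n_remove: int | None = None):
        """Subtract the modeled nuisance part: x_new = x - W (W' x).

        Removes the projection onto the first ``n_remove`` axes (all fitted
        axes by default).  Idempotent for a fixed axis set.
        """
        check_is_fitted(self, "components_")
        if n_remove is None:
            n_remove = self.components_.shape[0]
        if n_remove < 0:
            raise ValueError("n_remove must be non-negative")
        if n_remove > self.components_.shape[0]:
            raise ValueError("n_remove exceeds the number of fitted axes")
        X = np.asarray(X, dtype=float)
        Wd = self.components_[:n_remove]
        return X - (X @ Wd.T) @ Wd


def fit_oosda(
    X: np.ndarray, labels: np.ndarray, n_components: int, **kwargs
) -> OOSDA:
    """Functional wrapper: fit an :class:`OOSDA` model on N x p data."""
    return OOSDA(n_components=n_components, **kwargs).fit(X, labels)
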