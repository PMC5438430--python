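"""Removal of shift and batch effects via latent-variable subtraction.

The workflow: zero-impute missing cells, compress the spectra by PCA to
N - k dimensions (k chosen so the discriminant scatter matrices are
numerically non-singular), fit OOS-DA on the nuisance labels in the score
space, choose how many discriminant axes to remove by watching the spread
of anchor replicates (the one compound present in every batch), subtract
those axes, back-project to the spectral space, and reinstate the original
missing-value positions so no spurious features are introduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .discriminant import OOSDA
from .table import FeatureTable, ValidationError, align_metadata

__all__ = [
    "PcaCompression",
    "TuningCurve",
    "pca_compress",
    "centroid_spread_b",
    "tune_dimension",
    "LatentNuisanceCorrector",
    "PCASubtractor",
    "correct_unwanted_variation",
    "pca_subtract",
    "merge_replicates",
    "shift_labels",
]


@dataclass
class PcaCompression:
    """Mean + orthonormal loadings + scores: a lossless-within-rank
    round-trip between spectral space (p dims) and score space (N-k dims)."""

    mean: np.ndarray            # p-vector
    loadings: np.ndarray        # p x (N-k), orthonormal columns
    scores: np.ndarray          # (N-k) x N, one column per sample
    k: int

    def compress(self, X: np.ndarray) -> np.ndarray:
        """Columns of X (p x M) -> score columns ((N-k) x M)."""
        return self.loadings.T @ (X - self.mean[:, None])

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Score columns -> spectral columns (p x M)."""
        return self.mean[:, None] + self.loadings @ scores


@dataclass
class TuningCurve:
    """Anchor-replicate spread b(d) as a function of removed dimensions."""

    dims: np.ndarray
    b_values: np.ndarray
    d_best: int
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"d": self.dims, "b": self.b_values})


def _zero_imputed(table: FeatureTable) -> np.ndarray:
    return np.where(table.missing_mask, 0.0, table.values)


def pca_compress(table: FeatureTable, k: int) -> PcaCompression:
    """Column-mean-centered PCA keeping the top N - k components.

    Missing cells are imputed to 0 first (non-detection reads as zero
    intensity in the upstream export).  k trades reconstruction fidelity
    for non-singular within-class scatter downstream.
    """
    N = table.n_samples
    if k >= N - 1:
        raise ValidationError(f"k={k} must be < N-1={N - 1}")
    X = _zero_imputed(table)  # p x N
    # at most min(p, N) directions exist; N-k is the target dimension
    n_comp = min(N - k, table.n_features)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X.T)  # N x (N-k)
    return PcaCompression(
        mean=pca.mean_, loadings=pca.components_.T, scores=scores.T, k=k
    )


def centroid_spread_b(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average Euclidean distance between class centroids and their
    unweighted global centroid:

        b = (1/K) sum_k || m_k - m ||,   m = (1/K) sum_k m_k.

    ``scores`` has one sample per column (d x N).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("need at least two classes for the spread b")
    centroids = np.stack(
        [scores[:, labels == c].mean(axis=1) for c in classes], axis=1
    )
    global_centroid = centroids.mean(axis=1)
    return float(
        np.linalg.norm(centroids - global_centroid[:, None], axis=0).mean()
    )


def _select_d_best(b: np.ndarray, rel_tol: float) -> tuple[int, bool]:
    """Smallest d with |b(d+1) - b(d)| / b(d) < rel_tol; else d_max."""
    for i in range(len(b) - 1):
        if b[i] == 0 or abs(b[i + 1] - b[i]) / abs(b[i]) < rel_tol:
            return i + 1, True
    return len(b), False


def tune_dimension(
    compression: PcaCompression,
    nuisance_labels: np.ndarray,
    anchor_idx: np.ndarray,
    anchor_labels: np.ndarray,
    d_max: int,
    rel_tol: float = 0.01,
) -> TuningCurve:
    """Pick how many discriminant axes to subtract.

    For each d = 1..d_max, fit OOS-DA on the nuisance labels in the
    compressed score space, remove the first d axes, and measure the
    anchor-replicate spread b(d) (anchors grouped by their batch).  The
    chosen d_best is the smallest dimension where b(d) has stabilized:
    |b(d+1) - b(d)| / b(d) < rel_tol (default 1%).  Since the OOS-DA axes
    are sequential, a single fit with d_max components yields every b(d).
    """
    S = compression.scores  # (N-k) x N
    model = OOSDA(n_components=d_max).fit(S.T, nuisance_labels)
    b = np.empty(d_max)
    for d in range(1, d_max + 1):
        cleaned = model.remove(S.T, n_remove=d).T
        b[d - 1] = centroid_spread_b(cleaned[:, anchor_idx], anchor_labels)
    d_best, converged = _select_d_best(b, rel_tol)
    if not converged:
        warnings.warn(
            f"spread b(d) never stabilized below {rel_tol:.2%}; "
            f"using d_best = d_max = {d_max}",
            stacklevel=2,
        )
    return TuningCurve(np.arange(1, d_max + 1), b, d_best, converged)


class LatentNuisanceCorrector(TransformerMixin, BaseEstimator):
    """Supervised removal of nuisance variation (scikit-learn interface).

    ``fit(X, y)`` learns the PCA compression and the OOS-DA nuisance axes
    from samples-in-rows data ``X`` with nuisance labels ``y`` (e.g. batch
    ids, or a pre/post indicator for an injection-order shift);
    ``transform`` subtracts the chosen axes and back-projects.

    Parameters
    ----------
    k : int, default 2
        PCA pre-compression parameter: spectra are compressed to N - k
        dimensions.  2 suits a two-level shift nuisance, 8 a four-batch
        nuisance (k of the order of the class count keeps the within-class
        scatter well conditioned).
    d : int or "auto", default "auto"
        Number of discriminant axes to remove.  "auto" requires anchor
        information at fit time and applies the 1%-stabilization rule.
    d_max : int or None
        Largest dimension scanned during tuning; defaults to
        min(20, N - k - 1).
    rel_tol : float, default 0.01
        Stabilization threshold on the relative change of b(d).
    auto_raise_k : bool, default True
        If the within-class scatter is singular at the requested k, retry
        with larger k until it is well conditioned.
    """

    def __init__(
        self,
        k: int = 2,
        d="auto",
        d_max: int | None = None,
        rel_tol: float = 0.01,
        auto_raise_k: bool = True,
    ):
        self.k = k
        self.d = d
        self.d_max = d_max
        self.rel_tol = rel_tol
        self.auto_raise_k = auto_raise_k

    def fit(self, X, y, anchor_idx=None, anchor_labels=None):
        X = np.asarray(X, dtype=float)  # N x p
        y = np.asarray(y)
        N = X.shape[0]
        if len(np.unique(y)) < 2:
            raise ValueError("nuisance labels must have at least two levels")
        if np.isnan(X).any():
            raise ValueError("impute missing values before fitting")

        k = self.k
        while True:
            n_comp = min(N - k, X.shape[1])
            if n_comp < 2:
                raise ValueError("k too large for the sample count")
            pca = PCA(n_components=n_comp, svd_solver="full")
            scores = pca.fit_transform(X)  # N x (N-k)
            d_max = self.d_max or min(20, N - k - 1)
            d_max = min(d_max, n_comp)
            try:
                model = OOSDA(n_components=d_max).fit(scores, y)
                break
            except ValueError as err:
                if self.auto_raise_k and "singular" in str(err) and k < N - 3:
                    k += 1
                    continue
                raise

        self.compression_ = PcaCompression(
            mean=pca.mean_, loadings=pca.components_.T, scores=scores.T, k=k
        )
        self.model_ = model
        self.k_used_ = k

        if self.d == "auto":
            if anchor_idx is None or anchor_labels is None:
                raise ValueError(
                    "d='auto' tuning needs anchor_idx and anchor_labels"
                )
            curve = tune_dimension(
                self.compression_, y, np.asarray(anchor_idx),
                np.asarray(anchor_labels), d_max, self.rel_tol,
            )
            self.tuning_curve_ = curve
            self.d_ = curve.d_best
        else:
            self.d_ = int(self.d)
            if self.d_ > d_max:
                raise ValueError(f"d={self.d_} exceeds d_max={d_max}")
            self.tuning_curve_ = None
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Return X with the nuisance axes subtracted (back-projected)."""
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        scores = self.compression_.compress(X.T)  # (N-k) x M
        cleaned = self.model_.remove(scores.T, n_remove=self.d_).T
        return self.compression_.reconstruct(cleaned).T


class PCASubtractor(TransformerMixin, BaseEstimator):
    """Unsupervised alternative: subtract the top-q principal components.

    Removes the dominant variation regardless of labels — the comparison
    baseline for the supervised corrector.  q defaults to 3.
    """

    def __init__(self, q: int = 3):
        self.q = q

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        N = X.shape[0]
        if self.q >= N - 1:
            raise ValueError(f"q={self.q} must be < N-1={N - 1}")
        if self.q > 0:
            pca = PCA(n_components=self.q, svd_solver="full")
            pca.fit(X)
            self.mean_ = pca.mean_
            self.components_ = pca.components_
        else:
            self.mean_ = X.mean(axis=0)
            self.components_ = np.empty((0, X.shape[1]))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        C = X - self.mean_
        return X - (C @ self.components_.T) @ self.components_


# ----------------------------------------------------------------------
# FeatureTable-level wrappers


def shift_labels(meta: pd.DataFrame, shift_break: int) -> np.ndarray:
    """Two-level nuisance labels from an injection-order breakpoint:
    injections 1..shift_break vs the rest."""
    order = meta["injection_order"].to_numpy()
    return np.where(order <= shift_break, "pre", "post")


def _anchor_info(
    meta: pd.DataFrame, anchor_compound: str, nuisance_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor sample indices and their nuisance-class assignment.

    Tuning watches the spread of anchor-replicate centroids across the
    *nuisance* classes being removed (shift groups in step 6, batches in
    step 7): once the nuisance structure is gone those centroids collapse
    and b(d) stabilizes.
    """
    is_anchor = (meta["compound"] == anchor_compound).to_numpy()
    if not is_anchor.any():
        raise ValidationError(f"no samples of anchor compound {anchor_compound!r}")
    anchor_idx = np.nonzero(is_anchor)[0]
    anchor_classes = np.asarray(nuisance_labels)[anchor_idx]
    if len(np.unique(anchor_classes)) < 2:
        raise ValidationError(
            "anchor replicates must span at least two nuisance classes"
        )
    return anchor_idx, anchor_classes


def correct_unwanted_variation(
    table: FeatureTable,
    samples: pd.DataFrame,
    nuisance: str = "batch",
    k: int | None = None,
    d="auto",
    anchor_compound: str = "Mebendazole",
    shift_break: int | None = None,
    d_max: int | None = None,
    rel_tol: float = 0.01,
    nuisance_labels: np.ndarray | None = None,
) -> tuple[FeatureTable, LatentNuisanceCorrector]:
    """One supervised correction pass on a feature table.

    ``nuisance`` is "shift" (two classes split at ``shift_break`` in the
    injection order; k defaults to 2), "batch" (batch ids; k defaults to 8)
    or "custom" (explicit ``nuisance_labels``).  Missing-cell positions are
    saved before modeling and reinstated afterwards.
    """
    if table.scale != "log2":
        raise ValidationError("correction expects log2-scale data")
    meta = align_metadata(table, samples)
    if nuisance == "shift":
        if shift_break is None:
            raise ValidationError("shift nuisance requires shift_break")
        y = shift_labels(meta, shift_break)
        k = 2 if k is None else k
    elif nuisance == "batch":
        y = meta["batch"].to_numpy()
        k = 8 if k is None else k
    elif nuisance == "custom":
        if nuisance_labels is None:
            raise ValidationError("custom nuisance requires nuisance_labels")
        y = np.asarray(nuisance_labels)
        k = 2 if k is None else k
    else:
        raise ValidationError(f"unknown nuisance kind {nuisance!r}")

    mask = table.missing_mask.copy()
    X = np.where(mask, 0.0, table.values).T  # N x p

    corrector = LatentNuisanceCorrector(
        k=k, d=d, d_max=d_max, rel_tol=rel_tol
    )
    if d == "auto":
        anchor_idx, anchor_classes = _anchor_info(meta, anchor_compound, y)
        corrector.fit(X, y, anchor_idx=anchor_idx, anchor_labels=anchor_classes)
    else:
        corrector.fit(X, y)
    cleaned = corrector.transform(X).T  # p x N

    out = table.copy()
    out.values = np.where(mask, np.nan, cleaned)
    return out, corrector


def pca_subtract(table: FeatureTable, q: int = 3) -> FeatureTable:
    """Unsupervised comparison mode: subtract the first q principal
    components from every spectrum; missing cells reinstated."""
    if table.scale != "log2":
        raise ValidationError("PCA subtraction expects log2-scale data")
    mask = table.missing_mask.copy()
    X = np.where(mask, 0.0, table.values).T
    cleaned = PCASubtractor(q=q).fit(X).transform(X).T
    out = table.copy()
    out.values = np.where(mask, np.nan, cleaned)
    return out


def merge_replicates(
    table: FeatureTable, samples: pd.DataFrame
) -> tuple[FeatureTable, pd.DataFrame]:
    """Collapse replicate groups to their per-feature median.

    Missing cells are ignored in each median; a cell is missing in the
    merged table only when all replicates are missing.  Returns the merged
    table and collapsed per-group metadata (batch values joined with ';'
    when a group spans batches, as anchor replicates do).
    """
    meta = align_metadata(table, samples)
    groups: list[str] = []
    for g in meta["replicate_group"]:
        if g not in groups:
            groups.append(g)
    merged = np.full((table.n_features, len(groups)), np.nan)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN medians
        for j, g in enumerate(groups):
            cols = np.nonzero((meta["replicate_group"] == g).to_numpy())[0]
            merged[:, j] = np.nanmedian(table.values[:, cols], axis=1)
            sub = meta.iloc[cols]
            rows.append(
                {
                    "sample_id": g,
                    "sample_type": sub["sample_type"].iloc[0],
                    "batch": ";".join(dict.fromkeys(sub["batch"])),
                    "injection_order": int(sub["injection_order"].min()),
                    "replicate_group": g,
                    "compound": sub["compound"].iloc[0],
                    "class_label": sub["class_label"].iloc[0],
                }
            )
    out = FeatureTable(
        merged, table.feature_meta.copy().reset_index(drop=True),
        groups, table.scale,
    )
    return out, pd.DataFrame(rows).set_index("sample_id", drop=False)
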