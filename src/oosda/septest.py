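"""Separation scoring and the permutation significance test.

In high-dimensional spectra a discriminant method will find a visually
convincing separation between *any* labeling, including a random one, so a
score plot alone is never evidence of class structure.  The quantitative
guard used here is the separation score

    s_sep = b / w

where b is the average distance of class centroids from their global
centroid and w the average within-class distance of samples from their own
centroid, both measured in the low-dimensional discriminant space.  Its
null distribution is obtained by refitting the discriminant model on
permuted labels; the p-value positions the observed score within that
null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .correction import centroid_spread_b
from .discriminant import OOSDA
from .table import FeatureTable, ValidationError

__all__ = [
    "SeparationResult",
    "within_spread_w",
    "separation_score",
    "permutation_test",
    "permutation_test_matrix",
    "one_vs_rest_tests",
]


@dataclass
class SeparationResult:
    """Observed separation score, permutation null, and p-value."""

    s_obs: float
    p_value: float
    null_scores: np.ndarray
    d_latent: int
    n_perm: int
    seed: int | None

    def summary(self) -> str:
        return (
            f"s_sep = {self.s_obs:.3f}, p = {self.p_value:.4g} "
            f"({self.n_perm} permutations, {self.d_latent}-D latent space)"
        )


def within_spread_w(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average within-class distance from a sample to its class centroid:
    w = (1/K) sum_k (1/N_k) sum_{x in k} ||x - m_k||.  ``scores`` is d x N."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    w = 0.0
    for c in classes:
        block = scores[:, labels == c]
        m = block.mean(axis=1, keepdims=True)
        w += np.linalg.norm(block - m, axis=0).mean()
    return float(w / len(classes))


def separation_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """s_sep = b / w: between-class centroid spread over within-class
    spread.  Scale-invariant; larger means better separated classes."""
    w = within_spread_w(scores, labels)
    if w == 0:
        raise ValidationError("degenerate: zero within-class spread")
    return centroid_spread_b(scores, labels) / w


def permutation_test_matrix(
    X: np.ndarray,
    labels: np.ndarray,
    d_latent: int = 3,
    n_perm: int = 10_000,
    seed: int | None = None,
    k_precompress: int = 2,
    rng: np.random.Generator | None = None,
) -> SeparationResult:
    """Permutation test of class separation on samples-in-rows data.

    The spectra are PCA-compressed once to N - k dimensions (the
    compression ignores labels, so it is shared by every permutation); the
    observed score is s_sep of the OOS-DA scores on the true labels in the
    d_latent-dimensional space, and the null refits OOS-DA on each of
    ``n_perm`` uniformly permuted label vectors.  The add-one estimator
    p = (1 + #{s_null >= s_obs}) / (1 + n_perm) never reports zero.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    N = X.shape[0]
    if len(np.unique(labels)) < 2:
        raise ValidationError("need at least two classes")
    n_comp = min(N - k_precompress, X.shape[1])
    if n_comp < d_latent:
        raise ValidationError(
            f"d_latent={d_latent} exceeds available dimensions {n_comp}"
        )

    def score_for(scores: np.ndarray, y: np.ndarray) -> float:
        model = OOSDA(n_components=d_latent).fit(scores, y)
        return separation_score(model.transform(scores).T, y)

    # pre-compress once (label-independent, shared by all permutations);
    # if the within-class scatter of any labeling is too ill-conditioned
    # at N - k dimensions, restart the whole test with a larger k
    k = k_precompress
    while True:
        n_comp = min(N - k, X.shape[1])
        scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
        gen = np.random.default_rng(seed) if rng is None else rng
        try:
            s_obs = score_for(scores, labels)
            null = np.empty(n_perm)
            for i in range(n_perm):
                null[i] = score_for(scores, gen.permutation(labels))
            break
        except ValueError as err:
            if "singular" in str(err) and N - (k + 1) >= d_latent:
                k += 1
                continue
            raise
    p = (1 + int(np.sum(null >= s_obs))) / (1 + n_perm)
    return SeparationResult(s_obs, p, null, d_latent, n_perm, seed)


def permutation_test(
    table: FeatureTable,
    class_labels: np.ndarray,
    d_latent: int = 3,
    n_perm: int = 10_000,
    seed: int | None = None,
    k_precompress: int = 2,
) -> SeparationResult:
    """Permutation test on a feature table (missing cells imputed to 0 for
    the read-only modeling; the table itself is untouched)."""
    X = np.where(table.missing_mask, 0.0, table.values).T
    return permutation_test_matrix(
        X, class_labels, d_latent=d_latent, n_perm=n_perm, seed=seed,
        k_precompress=k_precompress,
    )


def one_vs_rest_tests(
    table: FeatureTable,
    class_labels: np.ndarray,
    classes: list | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Test each class against all other samples pooled.

    Returns a DataFrame with one row per contrast (class, s_obs, p_value).
    """
    class_labels = np.asarray(class_labels)
    if classes is None:
        classes = list(np.unique(class_labels))
    rows = []
    for c in classes:
        binary = np.where(class_labels == c, str(c), "rest")
        res = permutation_test(table, binary, **kwargs)
        rows.append({"class": c, "s_obs": res.s_obs, "p_value": res.p_value})
    return pd.DataFrame(rows)
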