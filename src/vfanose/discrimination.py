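"""Standardization, PCA and cluster-separation scoring of feature matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

__all__ = [
    "PcaResult",
    "SeparationResult",
    "standardize",
    "apply_standardization",
    "pca",
    "scree",
    "cluster_separation",
]


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray  # measurements x components
    loadings: np.ndarray  # features x components, orthonormal columns
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    feature_names: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class SeparationResult:
    score: float
    per_point: np.ndarray
    singleton_labels: tuple[str, ...] = ()


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    arr = np.asarray(X, dtype=float)
    return arr, tuple(f"f{i}" for i in range(arr.shape[1]))


def standardize(X):
    """Per-feature z-scoring (sample sd, denominator n-1).

    Returns ``(Z, means, sds)``.  A zero-variance column raises with the
    column named rather than being dropped silently.
    """
    arr, names = _as_matrix(X)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("standardize needs a 2-D matrix with >= 2 rows")
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    zero = np.nonzero(sds == 0.0)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance feature column(s): {[names[i] for i in zero]}"
        )
    Z = (arr - means) / sds
    if isinstance(X, pd.DataFrame):
        Z = pd.DataFrame(Z, index=X.index, columns=X.columns)
    return Z, means, sds


def apply_standardization(X, means, sds):
    """Re-apply stored transform parameters (for idempotence / new data)."""
    arr, _ = _as_matrix(X)
    return (arr - np.asarray(means)) / np.asarray(sds)


def pca(Z, n_components: int | None = None) -> PcaResult:
    """PCA of a standardized matrix via SVD.

    Components are eigenvectors of the sample covariance ordered by
    decreasing eigenvalue; scores are the data projected on them.  Sign
    convention: the largest-magnitude entry of each loading column is
    positive, so results are deterministic.  Requesting more components than
    the matrix rank truncates with a recorded warning.
    """
    arr, names = _as_matrix(Z)
    n_rows, n_cols = arr.shape
    if n_rows < 2:
        raise ValueError("pca needs >= 2 rows")
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    centered = arr - means

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / (n_rows - 1)
    total = float(var.sum())
    rank = int(np.sum(s > s[0] * max(n_rows, n_cols) * np.finfo(float).eps)) if s.size else 0

    warnings: list[str] = []
    k = min(rank, n_rows - 1, n_cols)
    if n_components is not None:
        if n_components > k:
            warnings.append(
                f"requested {n_components} components, rank allows {k}; truncated"
            )
        else:
            k = n_components
    loadings = vt[:k].T
    # deterministic sign: largest-|entry| of each loading column positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = centered @ loadings
    ratio = var[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance=var[:k],
        explained_variance_ratio=ratio,
        feature_means=means,
        feature_sds=sds,
        feature_names=names,
        warnings=tuple(warnings),
    )


def scree(result: PcaResult) -> np.ndarray:
    """Ordered (nonincreasing) explained-variance proportions."""
    return np.asarray(result.explained_variance_ratio)


def cluster_separation(
    scores: np.ndarray,
    labels,
    components: tuple[int, ...] = (1, 3),
) -> SeparationResult:
    """Mean silhouette of the labelled points on the selected score components
    (1-based PC indices, Euclidean distance).

    Labels with a single member get silhouette 0 and are reported in
    ``singleton_labels``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.size:
        raise ValueError("scores and labels must have the same length")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("cluster_separation needs >= 2 distinct labels")
    cols = [c - 1 for c in components]
    if min(cols) < 0 or max(cols) >= scores.shape[1]:
        raise ValueError(
            f"components {components} out of range for {scores.shape[1]} score columns"
        )
    sub = scores[:, cols]
    per_point = silhouette_samples(sub, labels)  # sklearn: singleton clusters -> 0
    singletons = tuple(str(u) for u, c in zip(uniq, counts) if c == 1)
    return SeparationResult(
        score=float(np.mean(per_point)),
        per_point=per_point,
        singleton_labels=singletons,
    )
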