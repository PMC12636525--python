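"""Habitat clustering of environmental samples.

Samples described by biogeochemical parameters (chlorophyll a, silicate,
temperature, salinity, pH, cell abundances, ...) are z-scaled and
clustered with k-means; the number of clusters is chosen by maximizing
the Calinski-Harabasz index over k = 2..k_max. A PCA summary of the same
scaled matrix supports visual inspection of the habitat structure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import InputError

logger = logging.getLogger(__name__)


def zscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each parameter column to mean 0 and sample SD 1 (ddof=1).

    Zero-variance columns carry no clustering information and are dropped
    with a warning.
    """
    if matrix.shape[0] < 2:
        raise InputError("z-scaling requires at least two samples")
    sd = matrix.std(ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("zscale: dropping constant columns %s", list(sd.index[~keep]))
    sub = matrix.loc[:, keep]
    return (sub - sub.mean()) / sub.std(ddof=1)


def calinski_harabasz(matrix, labels) -> float:
    """Calinski-Harabasz index: (B/(k-1)) / (W/(n-k)).

    B and W are the between- and within-cluster sums of squared Euclidean
    distances to centroids. Returns +inf when W == 0 (perfectly tight
    clusters).
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if not 1 < k < n:
        raise InputError(f"calinski_harabasz requires 1 < k < n (k={k}, n={n})")
    overall = X.mean(axis=0)
    B = W = 0.0
    for lab in uniq:
        pts = X[labels == lab]
        centroid = pts.mean(axis=0)
        W += float(((pts - centroid) ** 2).sum())
        B += len(pts) * float(((centroid - overall) ** 2).sum())
    if W == 0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def kmeans_select(
    matrix: pd.DataFrame,
    k_max: int = 8,
    runs: int = 10,
    seed: int = 0,
) -> tuple[int, pd.Series]:
    """Choose k in 2..k_max by the Calinski-Harabasz index.

    For each k, k-means (k-means++ initialization, ``runs`` restarts, best
    within-cluster sum of squares kept) is fit on the scaled matrix; the k
    maximizing the index wins, smaller k on ties. Deterministic given the
    seed.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise InputError("k selection requires at least 3 samples")
    if not 2 <= k_max < n:
        raise InputError(f"k_max must lie in [2, n_samples) (k_max={k_max}, n={n})")
    best_k, best_ch, best_labels = None, -np.inf, None
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=runs, random_state=seed).fit(X)
        ch = calinski_harabasz(X, km.labels_)
        if ch > best_ch:
            best_k, best_ch, best_labels = k, ch, km.labels_
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(n)
    return best_k, pd.Series(best_labels, index=index, name="cluster")


def pca(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Centered SVD principal component analysis.

    Returns (scores, loadings, variance fractions). Component signs are
    fixed by making each loading vector's largest-magnitude element
    positive, so results are reproducible across SVD implementations.
    ``scores @ loadings.T`` reconstructs the centered matrix.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise InputError("PCA requires at least 2 samples")
    centered = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    loadings = Vt.T
    scores = U * s
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    total = float((s ** 2).sum())
    var_frac = (s ** 2) / total if total > 0 else np.zeros_like(s)
    comp = [f"PC{i + 1}" for i in range(len(s))]
    if isinstance(matrix, pd.DataFrame):
        scores_df = pd.DataFrame(scores, index=matrix.index, columns=comp)
        loadings_df = pd.DataFrame(loadings, index=matrix.columns, columns=comp)
    else:
        scores_df = pd.DataFrame(scores, columns=comp)
        loadings_df = pd.DataFrame(loadings, columns=comp)
    return scores_df, loadings_df, var_frac
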