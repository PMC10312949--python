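"""Cluster-typing metrics: m/c-scores, anatomy-aware soma distances, SVM overlap.

The central quantity is the exponential cluster-similarity score

    score(A, B) = exp( -2 * D_inter / ( (D_intra(A) + D_intra(B)) / 2 ) )

where ``D_inter`` is the Manhattan distance between the per-feature cluster
centers and ``D_intra(X)`` is the mean over samples of the mean Manhattan
distance to all other samples of the same cluster. Applied to morphometric
features it is the *m-score*; applied to connectivity barcodes, the
*c-score*. Identical clusters score 1; well-separated tight clusters score
near 0.

Soma spatial structure within an s-type is measured by a Mahalanobis
distance whose covariance comes from the voxel coordinates of the host
anatomical region (somas first mirrored to the canonical hemisphere), as the
squared form with no square root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine
from sklearn.svm import SVC

from .atlas import AnnotationVolume

__all__ = [
    "ClusterPairScore",
    "mc_score",
    "standardize",
    "score_matrix",
    "ratio_matrix",
    "display_order",
    "cosine_similarity_matrix",
    "pairwise_mahalanobis",
    "soma_distance_map",
    "dmap_similarity_correlation",
    "svm_overlap",
    "pca_augment",
]


# ---------------------------------------------------------------------- m/c-score

@dataclass
class ClusterPairScore:
    dist_inter: float
    dist_intra_1: float
    dist_intra_2: float
    score: float


def _mean_intra_manhattan(X: np.ndarray) -> float:
    """Mean over samples of the mean Manhattan distance to the other samples."""
    n = len(X)
    if n < 2:
        return 0.0
    D = cdist(X, X, metric="cityblock")
    return float((D.sum(axis=1) / (n - 1)).mean())


def mc_score(features_a: np.ndarray, features_b: np.ndarray) -> ClusterPairScore:
    """Exponential similarity between two clusters of feature rows.

    Inputs are expected to be standardized on the pooled comparison set (see
    :func:`standardize`; :func:`score_matrix` does this for you). Degenerate
    cases: when both intra-class distances are 0 (e.g. two singletons) the
    score is 1 if the centers coincide and 0 otherwise.
    """
    A = np.atleast_2d(np.asarray(features_a, dtype=float))
    B = np.atleast_2d(np.asarray(features_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    inter = float(np.abs(A.mean(axis=0) - B.mean(axis=0)).sum())
    intra1 = _mean_intra_manhattan(A)
    intra2 = _mean_intra_manhattan(B)
    denom = 0.5 * (intra1 + intra2)
    if denom == 0.0:
        score = 1.0 if inter == 0.0 else 0.0
    else:
        score = float(np.exp(-2.0 * inter / denom))
    return ClusterPairScore(inter, intra1, intra2, score)


def standardize(groups: list[np.ndarray]) -> list[np.ndarray]:
    """Z-score every feature over the pooled comparison set.

    Features spanning several orders of magnitude would otherwise dominate
    Manhattan distances. Zero-variance features are left centered.
    """
    pooled = np.vstack([np.atleast_2d(g) for g in groups]).astype(float)
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd[sd == 0] = 1.0
    return [(np.atleast_2d(g) - mu) / sd for g in groups]


def score_matrix(groups: list[np.ndarray], standardize_features: bool = True) -> pd.DataFrame:
    """Pairwise m/c-score matrix over a list of clusters (symmetric)."""
    gs = standardize(groups) if standardize_features else [np.atleast_2d(g) for g in groups]
    k = len(gs)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            s = mc_score(gs[i], gs[j]).score
            out[i, j] = out[j, i] = s
    return pd.DataFrame(out)


def ratio_matrix(c_scores: pd.DataFrame, m_scores: pd.DataFrame) -> pd.DataFrame:
    """Elementwise c-score / m-score; entries with m-score 0 become NaN."""
    if c_scores.shape != m_scores.shape:
        raise ValueError("score matrices must share shape and order")
    c = c_scores.to_numpy(dtype=float)
    m = m_scores.to_numpy(dtype=float)
    out = np.full_like(c, np.nan)
    np.divide(c, m, out=out, where=m != 0)
    return pd.DataFrame(out, index=c_scores.index, columns=c_scores.columns)


def display_order(m_scores: pd.DataFrame) -> np.ndarray:
    """Row order for heatmap display: Ward/Euclidean dendrogram leaf order."""
    Z = linkage(m_scores.to_numpy(), method="ward", metric="euclidean")
    return leaves_list(Z)


# --------------------------------------------------------------- neuron similarity

def cosine_similarity_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity; all-zero rows get similarity 0, diagonal 1."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    S = _sk_cosine(X) if (norms > 0).all() else np.zeros((len(X), len(X)))
    if not (norms > 0).all():
        ok = norms > 0
        if ok.any():
            S[np.ix_(ok, ok)] = _sk_cosine(X[ok])
    np.fill_diagonal(S, 1.0)
    return S


# ------------------------------------------------------------- anatomy distance map

def pairwise_mahalanobis(points: np.ndarray, cov: np.ndarray, sqrt: bool = False) -> np.ndarray:
    """Pairwise ``(p_i - p_j)^T Cov^{-1} (p_i - p_j)`` (squared form by default).

    Under the identity covariance this is the squared Euclidean distance.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    cov_inv = np.linalg.inv(np.asarray(cov, dtype=float))
    diff = P[:, None, :] - P[None, :, :]
    d2 = np.einsum("ijk,kl,ijl->ij", diff, cov_inv, diff)
    d2 = np.maximum(d2, 0.0)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2) if sqrt else d2


def soma_distance_map(
    somas: np.ndarray,
    region_id: int,
    atlas: AnnotationVolume,
    sqrt: bool = False,
    canonical_side: str = "left",
    ridge: float = 1e-6,
) -> np.ndarray:
    """Pairwise anatomy-aware Mahalanobis soma distances within one s-type.

    All somas are mirrored to the canonical hemisphere; the covariance is
    that of the ipsilateral region's voxel-center coordinates (μm). Entries
    are the squared form ``(s_i - s_j)^T Cov^{-1} (s_i - s_j)``; ``sqrt=True``
    returns the conventional rooted distance instead. A singular covariance
    is ridge-regularized (``ridge * trace/3`` on the diagonal).
    """
    somas = np.atleast_2d(np.asarray(somas, dtype=float))
    if len(somas) < 2:
        raise ValueError("need at least 2 somas")
    mirrored = atlas.mirror_to_hemisphere(somas, side=canonical_side)
    vox = atlas.region_voxels(region_id)
    if len(vox) < 4:
        raise ValueError(f"region {region_id} has too few voxels for a covariance")
    centers = atlas.voxel_center(vox)
    centers = atlas.mirror_to_hemisphere(centers, side=canonical_side)
    centers = np.unique(np.round(centers, 6), axis=0)
    cov = np.cov(centers.T)
    if np.linalg.cond(cov) > 1e12:
        cov = cov + np.eye(3) * (ridge * np.trace(cov) / 3.0)
    return pairwise_mahalanobis(mirrored, cov, sqrt=sqrt)


def dmap_similarity_correlation(dmap: np.ndarray, sim: np.ndarray) -> float:
    """Pearson correlation between the strictly-upper-triangle entries.

    Returns NaN when either vector is constant (undefined correlation).
    """
    dmap = np.asarray(dmap, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if dmap.shape != sim.shape:
        raise ValueError("matrices must share shape and neuron order")
    iu = np.triu_indices_from(dmap, k=1)
    x, y = dmap[iu], sim[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(pearsonr(x, y)[0])


# -------------------------------------------------------------------- SVM overlap

def svm_overlap(
    class_a: np.ndarray,
    class_b: np.ndarray,
    cost: float = 1000.0,
) -> float:
    """Pairwise class overlap (%) by linear-SVM resubstitution error.

    Fits a linear soft-margin SVM (C = ``cost``) on the two classes and
    reports the misclassified fraction x 100 on the training set. 0 means
    perfectly separable; ~50 means indistinguishable.
    """
    A = np.atleast_2d(np.asarray(class_a, dtype=float))
    B = np.atleast_2d(np.asarray(class_b, dtype=float))
    if len(A) < 5 or len(B) < 5:
        raise ValueError("each class needs at least 5 samples")
    X = np.vstack([A, B])
    y = np.concatenate([np.zeros(len(A)), np.ones(len(B))])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    clf = SVC(kernel="linear", C=cost)
    clf.fit(Xs, y)
    return float(np.mean(clf.predict(Xs) != y) * 100.0)


def pca_augment(
    m_features: np.ndarray,
    connectivity: np.ndarray,
    n_components: int = 3,
) -> np.ndarray:
    """Append the top principal-component scores of the connectivity matrix.

    The connectivity matrix is column-centered by the PCA itself; the
    returned array has ``m_features.shape[1] + n_components`` columns and is
    the feature space in which class overlap is re-measured.
    """
    M = np.atleast_2d(np.asarray(m_features, dtype=float))
    C = np.atleast_2d(np.asarray(connectivity, dtype=float))
    if len(M) != len(C):
        raise ValueError("feature and connectivity row counts differ")
    n_components = min(n_components, min(C.shape) - 1) or 1
    scores = PCA(n_components=n_components, random_state=0).fit_transform(C)
    return np.hstack([M, scores])
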