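"""Spatially tuned connectivity subtyping within one s-type.

Two pairwise matrices are combined: the cosine similarity of connectivity
barcodes (MC) and a Gaussian affinity of anatomy-aware soma distances
(MDA = exp(-MD ⊙ MD) on the min-max-normalized distance map MD). Their
Hadamard product A = MC ⊙ MDA is hierarchically clustered (Ward linkage on
1 − A) and the cluster count is selected by the Calinski-Harabasz index,
computed on the rows of A as feature vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import calinski_harabasz_score

from .metrics import cosine_similarity_matrix

__all__ = ["AffinityBundle", "SubtypeResult", "build_affinity", "subtype",
           "subtype_report"]

log = logging.getLogger(__name__)


@dataclass
class AffinityBundle:
    """MC, MD, MDA and the combined affinity A over one neuron set."""

    MC: np.ndarray            # cosine barcode similarity, min-max normalized
    MD: np.ndarray            # soma distance map, min-max normalized
    MDA: np.ndarray           # exp(-MD ⊙ MD)
    A: np.ndarray             # MC ⊙ MDA, diagonal forced to max
    neuron_ids: list = field(default_factory=list)
    kept: np.ndarray | None = None   # indices kept after zero-barcode exclusion


@dataclass
class SubtypeResult:
    labels: np.ndarray        # 1..k per neuron
    k: int
    ch_scores: dict           # candidate k -> Calinski-Harabasz score
    linkage_tree: np.ndarray
    bundle: AffinityBundle


def _minmax_offdiag(M: np.ndarray) -> np.ndarray:
    """Min-max normalize using only off-diagonal entries (diagonal mapped too)."""
    out = np.array(M, dtype=float)
    mask = ~np.eye(len(out), dtype=bool)
    lo, hi = out[mask].min(), out[mask].max()
    if hi > lo:
        out = (out - lo) / (hi - lo)
    else:
        out = np.zeros_like(out)
    return np.clip(out, 0.0, 1.0)


def build_affinity(
    barcodes: np.ndarray,
    dmap: np.ndarray,
    neuron_ids: list | None = None,
) -> AffinityBundle:
    """Combine barcode similarity and soma adjacency into one affinity.

    All-zero barcode rows carry no connectivity signal and are excluded
    (logged) before normalization; ``kept`` records the surviving indices.
    MC and MD are min-max normalized over off-diagonal entries, MDA is the
    Gaussian kernel of MD, and A = MC ⊙ MDA with its diagonal forced to the
    matrix maximum so self-affinity never undercuts any pair.
    """
    B = np.atleast_2d(np.asarray(barcodes, dtype=float))
    D = np.asarray(dmap, dtype=float)
    if len(B) != len(D):
        raise ValueError("barcodes and dmap must share neuron order")
    if len(B) < 3:
        raise ValueError("need at least 3 neurons")
    ids = list(neuron_ids) if neuron_ids is not None else list(range(len(B)))
    nonzero = np.linalg.norm(B, axis=1) > 0
    if not nonzero.all():
        log.warning("excluding %d all-zero barcode rows", int((~nonzero).sum()))
    kept = np.flatnonzero(nonzero)
    if len(kept) < 3:
        raise ValueError("fewer than 3 neurons with nonzero barcodes")
    B = B[kept]
    D = D[np.ix_(kept, kept)]
    ids = [ids[i] for i in kept]

    MC = _minmax_offdiag(cosine_similarity_matrix(B))
    MD = _minmax_offdiag(D)
    MDA = np.exp(-MD * MD)
    A = MC * MDA
    np.fill_diagonal(A, A.max())
    return AffinityBundle(MC=MC, MD=MD, MDA=MDA, A=A, neuron_ids=ids, kept=kept)


def subtype(bundle: AffinityBundle, k_range=None) -> SubtypeResult:
    """Cluster the combined affinity and select k by Calinski-Harabasz.

    Ward linkage is applied to the dissimilarity D = 1 − A; every candidate
    k cuts the same tree, and the k maximizing the CH index (rows of A as
    feature vectors) wins.
    """
    A = bundle.A
    n = len(A)
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError(f"no valid candidate k for n={n}")
    if max(k_range) > n - 1:
        log.warning("k range truncated to %d for n=%d", max(ks), n)
    D = 1.0 - A
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Z = linkage(squareform(D, checks=False), method="ward")
    ch: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        labels = fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = labels
        if len(np.unique(labels)) < 2:
            ch[k] = float("-inf")
            continue
        ch[k] = float(calinski_harabasz_score(A, labels))
    best_k = max(ks, key=lambda k: ch[k])
    return SubtypeResult(
        labels=labels_by_k[best_k],
        k=best_k,
        ch_scores=ch,
        linkage_tree=Z,
        bundle=bundle,
    )


def subtype_report(
    result: SubtypeResult,
    barcodes: np.ndarray,
    domain_ids: list,
    somas: np.ndarray | None = None,
    projection: pd.DataFrame | None = None,
) -> dict:
    """Per-cluster summaries: size, soma centroid, mean barcode, top targets.

    ``barcodes`` and ``somas`` must be in the bundle's (kept) neuron order.
    When a regional projection-length matrix is supplied its per-cluster
    mean profile is included. Also returns the display ordering of neurons
    grouped by cluster.
    """
    B = np.atleast_2d(np.asarray(barcodes, dtype=float))
    labels = result.labels
    clusters = []
    for c in sorted(np.unique(labels)):
        sel = labels == c
        mean_bc = B[sel].mean(axis=0)
        top = np.argsort(mean_bc)[::-1][:5]
        entry = {
            "cluster": int(c),
            "size": int(sel.sum()),
            "mean_barcode": mean_bc.tolist(),
            "top_targets": [str(domain_ids[t]) for t in top if mean_bc[t] > 0],
        }
        if somas is not None:
            entry["soma_centroid_um"] = np.asarray(somas)[sel].mean(axis=0).tolist()
        if projection is not None:
            entry["mean_projection_um"] = projection.iloc[sel].mean(axis=0).to_dict()
        clusters.append(entry)
    order = np.argsort(labels, kind="stable")
    return {
        "k": result.k,
        "ch_scores": {int(k): v for k, v in result.ch_scores.items()},
        "clusters": clusters,
        "display_order": order.tolist(),
    }
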