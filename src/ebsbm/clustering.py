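"""Candidate partitions via regularized spectral clustering.

The shrinkage estimator and the selection criterion accept a partition
from any community-detection front-end; this module provides a robust
default.  The adjacency is degree-regularized (a small constant is added
to every dyad, which keeps the normalized Laplacian well conditioned on
sparse graphs and for isolated nodes), the top-k eigenvectors of the
symmetrically normalized matrix are row-normalized, and k-means with
multiple restarts assigns communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .graphs import Graph, Partition


@dataclass
class ClusterConfig:
    k_range: list[int] = field(default_factory=lambda: list(range(1, 21)))
    seed: int = 0
    regularizer: float = 1.0
    kmeans_restarts: int = 20

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.k_range):
            raise ValueError("all k_range values must be >= 1")
        if self.regularizer < 0:
            raise ValueError("regularizer must be nonnegative")
        if self.kmeans_restarts < 1:
            raise ValueError("kmeans_restarts must be positive")


def _spectral_embedding(g: Graph, k: int, regularizer: float) -> np.ndarray:
    """Top-k eigenvectors of the regularized, normalized adjacency, row-normalized."""
    n = g.n
    avg_degree = g.adjacency.sum() / n
    tau = regularizer * avg_degree / n
    a = g.adjacency.astype(np.float64) + tau
    d = a.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(d)
    m = a * d_isqrt[:, None] * d_isqrt[None, :]
    # top-k eigenvectors of the normalized adjacency == bottom-k of the
    # normalized Laplacian I - M
    _, vecs = scipy.linalg.eigh(m, subset_by_index=[n - k, n - 1])
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1.0
    return vecs / norms[:, None]


def spectral_partition(g: Graph, k: int, cfg: ClusterConfig) -> Partition:
    """Partition the nodes of ``g`` into ``k`` communities.

    Deterministic given (graph, k, cfg.seed).  For k=1 the trivial
    single-community partition is returned without computation.  If
    k-means leaves a cluster empty, the fit is retried with fresh seeded
    initializations up to 5 times, then the partition is compacted to its
    realized number of communities.
    """
    n = g.n
    if k > n:
        raise ValueError(f"k={k} exceeds the number of nodes n={n}")
    if k == 1:
        return Partition(np.ones(n, dtype=np.int64), K=1)
    if g.n_edges == 0:
        raise ValueError("graph has no edges; cannot cluster with k > 1")

    try:
        emb = _spectral_embedding(g, k, cfg.regularizer)
    except scipy.linalg.LinAlgError:
        # one retry with a stronger regularizer before giving up
        emb = _spectral_embedding(g, k, 10.0 * max(cfg.regularizer, 1.0))

    labels = None
    for attempt in range(6):
        km = KMeans(n_clusters=k, n_init=cfg.kmeans_restarts, random_state=cfg.seed + attempt)
        cand = km.fit_predict(emb)
        if np.unique(cand).size == k:
            labels = cand
            break
        labels = cand
    return Partition(labels + 1, K=k).compact()


def candidate_partitions(g: Graph, cfg: ClusterConfig) -> list[Partition]:
    """One partition per K in ``cfg.k_range``, each from spectral_partition.

    Partitions are reported with their realized community count, which can
    be below the requested K if clusters came out empty.
    """
    return [spectral_partition(g, k, cfg) for k in cfg.k_range]
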