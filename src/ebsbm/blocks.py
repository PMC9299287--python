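"""Block summaries of a graph under a partition, and the blockwise MLE.

A block (a, b) is the set of unordered node pairs with one endpoint in
community a and the other in b.  Its dyad capacity is
n_ab = n_a * n_b for a != b and n_aa = n_a (n_a - 1) / 2, and the block
edge count X^B_ab is Binomial(n_ab, theta_ab) under the SBM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graphs import Graph, Partition

logger = logging.getLogger(__name__)


@dataclass
class BlockStats:
    """Per-block edge counts and dyad capacities under a partition."""

    K: int
    edge_counts: np.ndarray  # symmetric K x K, X^B_ab
    capacities: np.ndarray   # symmetric K x K, n_ab

    def __post_init__(self) -> None:
        self.edge_counts = np.asarray(self.edge_counts, dtype=np.int64)
        self.capacities = np.asarray(self.capacities, dtype=np.int64)
        if self.edge_counts.shape != (self.K, self.K) or self.capacities.shape != (self.K, self.K):
            raise ValueError("edge_counts and capacities must be K x K")
        if np.any(self.edge_counts < 0) or np.any(self.edge_counts > self.capacities):
            raise ValueError("require 0 <= X^B_ab <= n_ab for every block")

    def diagonal(self) -> tuple[np.ndarray, np.ndarray]:
        """(counts, capacities) of the K diagonal blocks."""
        return np.diagonal(self.edge_counts).copy(), np.diagonal(self.capacities).copy()

    def offdiagonal(self) -> tuple[np.ndarray, np.ndarray]:
        """(counts, capacities) of the K(K-1)/2 upper-triangle blocks."""
        iu = np.triu_indices(self.K, k=1)
        return self.edge_counts[iu], self.capacities[iu]


@dataclass
class ConnectivityEstimate:
    """A K x K connection-probability estimate with its shrinkage factors."""

    theta: np.ndarray
    shrinkage: np.ndarray
    method: str  # "MLE", "EB", or "fixed-prior"

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.shrinkage = np.asarray(self.shrinkage, dtype=np.float64)
        if not np.allclose(self.theta, self.theta.T):
            raise ValueError("theta must be symmetric")
        if np.any(self.theta < 0) or np.any(self.theta > 1):
            raise ValueError("theta entries must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.theta.shape[0]


def block_counts(g: Graph, z: Partition) -> BlockStats:
    """Summarize ``g`` under partition ``z`` into block counts and capacities."""
    if z.n != g.n:
        raise ValueError(f"partition covers {z.n} nodes but graph has {g.n}")
    K = z.K
    onehot = np.zeros((g.n, K), dtype=np.int64)
    onehot[np.arange(g.n), z.labels - 1] = 1
    raw = onehot.T @ g.adjacency.astype(np.int64) @ onehot
    counts = raw.copy()
    np.fill_diagonal(counts, np.diagonal(raw) // 2)
    sizes = z.sizes
    caps = np.outer(sizes, sizes)
    np.fill_diagonal(caps, sizes * (sizes - 1) // 2)
    return BlockStats(K=K, edge_counts=counts, capacities=caps)


def mle_theta(stats: BlockStats) -> ConnectivityEstimate:
    """Blockwise empirical edge frequency X^B_ab / n_ab.

    Zero-capacity blocks (empty or singleton communities) get value 0 by
    convention, keeping downstream mean-squared errors finite.
    """
    caps = stats.capacities
    if np.any(caps == 0):
        logger.debug("mle_theta: %d zero-capacity block(s) set to 0", int((caps == 0).sum()))
    theta = np.divide(
        stats.edge_counts, caps, out=np.zeros_like(stats.edge_counts, dtype=np.float64), where=caps > 0
    )
    return ConnectivityEstimate(theta=theta, shrinkage=np.zeros_like(theta), method="MLE")
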