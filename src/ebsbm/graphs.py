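"""Graph and partition data model with edge-list / MatrixMarket / label I/O.

Graphs are undirected and simple: the adjacency matrix is binary,
symmetric, and hollow (no self loops).  Node indices are 0-based
internally; community labels are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)


class GraphFormatError(ValueError):
    """Raised when an input file does not describe a valid simple graph."""


@dataclass
class Graph:
    """An undirected simple graph stored as a dense 0/1 adjacency matrix."""

    adjacency: np.ndarray
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise GraphFormatError("adjacency must be a square matrix")
        if not np.array_equal(a, a.T):
            raise GraphFormatError("adjacency must be symmetric")
        if np.any((a != 0) & (a != 1)):
            raise GraphFormatError("adjacency entries must be 0 or 1")
        if np.any(np.diagonal(a) != 0):
            raise GraphFormatError("self loops are not allowed (diagonal must be 0)")
        self.adjacency = a.astype(np.int8, copy=False)
        if self.node_ids is not None and len(self.node_ids) != a.shape[0]:
            raise GraphFormatError("node_ids length does not match adjacency size")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        """Edge density 2m / (n(n-1))."""
        if self.n < 2:
            return 0.0
        return 2.0 * self.n_edges / (self.n * (self.n - 1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self.n == other.n and np.array_equal(self.adjacency, other.adjacency)


@dataclass
class Partition:
    """A node-to-community assignment with 1-based community labels.

    ``K`` is the declared number of communities; communities may be empty
    (e.g. the ground truth of a simulated graph where a label was never
    drawn).  ``compact()`` removes empty communities and renumbers.
    """

    labels: np.ndarray
    K: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D array")
        if self.K == 0:
            self.K = int(self.labels.max())
        if self.labels.min() < 1 or self.labels.max() > self.K:
            raise ValueError("labels must lie in 1..K")

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def sizes(self) -> np.ndarray:
        """Per-community node counts n_1, ..., n_K (zeros allowed)."""
        return np.bincount(self.labels, minlength=self.K + 1)[1:]

    @property
    def n_nonempty(self) -> int:
        return int(np.count_nonzero(self.sizes))

    def compact(self) -> "Partition":
        """Drop empty communities, renumbering labels to 1..K' by first use."""
        present = np.unique(self.labels)
        remap = np.zeros(self.K + 1, dtype=np.int64)
        remap[present] = np.arange(1, present.size + 1)
        return Partition(remap[self.labels], K=present.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.K == other.K and np.array_equal(self.labels, other.labels)


def load_edge_list(path, directed: bool = False) -> Graph:
    """Read a whitespace-separated edge list into an undirected simple graph.

    Each non-comment line holds two node tokens.  Arc orientations are
    dropped (every arc contributes an undirected edge), duplicate edges
    collapse to one, and self loops are discarded with a logged count.
    Node order follows first appearance in the file.
    """
    index: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    n_self_loops = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise GraphFormatError(
                    f"{path}: line {lineno}: expected two node tokens, got {len(tokens)}"
                )
            n_lines += 1
            ij = []
            for tok in tokens:
                if tok not in index:
                    index[tok] = len(index)
                ij.append(index[tok])
            i, j = ij
            if i == j:
                n_self_loops += 1
                continue
            edges.append((i, j))
    if n_lines == 0:
        raise GraphFormatError(f"{path}: no edges found")
    if n_self_loops:
        logger.warning("%s: dropped %d self loop(s)", path, n_self_loops)
    n = len(index)
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = 1
        a[j, i] = 1
    node_ids = [tok for tok, _ in sorted(index.items(), key=lambda kv: kv[1])]
    return Graph(a, node_ids=node_ids)


def save_adjacency(g: Graph, path) -> None:
    """Write the adjacency pattern as MatrixMarket coordinate/pattern/symmetric."""
    coo = sp.coo_matrix(g.adjacency)
    mmwrite(str(path), coo, field="pattern", symmetry="symmetric")


def load_adjacency(path) -> Graph:
    """Read a MatrixMarket adjacency matrix back into a Graph.

    The stored pattern is validated: it must be square, symmetric, binary
    and hollow.  Round-trips with :func:`save_adjacency`.
    """
    m = mmread(str(path))
    a = np.asarray(m.todense() if sp.issparse(m) else m)
    if np.any((a != 0) & (a != 1)):
        raise GraphFormatError(f"{path}: adjacency entries must be 0 or 1")
    return Graph(a.astype(np.int8))


def load_labels(path, g: Graph) -> Partition:
    """Read a two-column TSV of (node token, label token) into a Partition.

    Labels are compacted to 1..K in first-appearance order of the label
    tokens.  Every node of ``g`` must receive exactly one label.
    """
    if g.node_ids is None:
        node_index = {str(i): i for i in range(g.n)}
    else:
        node_index = {tok: i for i, tok in enumerate(g.node_ids)}
    label_index: dict[str, int] = {}
    labels = np.zeros(g.n, dtype=np.int64)
    seen = np.zeros(g.n, dtype=bool)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise GraphFormatError(
                    f"{path}: line {lineno}: expected node and label tokens"
                )
            node_tok, label_tok = tokens
            if node_tok not in node_index:
                raise GraphFormatError(f"{path}: line {lineno}: unknown node {node_tok!r}")
            if label_tok not in label_index:
                label_index[label_tok] = len(label_index) + 1
            i = node_index[node_tok]
            labels[i] = label_index[label_tok]
            seen[i] = True
    if not seen.all():
        missing = [
            (g.node_ids[i] if g.node_ids else str(i))
            for i in np.flatnonzero(~seen)
        ]
        raise GraphFormatError(f"{path}: nodes missing a label: {missing}")
    return Partition(labels, K=len(label_index))
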