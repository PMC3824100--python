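"""Undirected simple binary graphs and elementary structural queries.

Every other module works on :class:`Graph`: a labelled, 0-indexed,
undirected simple graph stored as a dense 0/1 adjacency matrix.  Degrees
``k`` and the edge count ``m`` are derived from the adjacency matrix and
kept consistent by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _scipy_components

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "SignVector",
    "TernaryVector",
    "build_graph",
    "from_adjacency",
    "connected_components",
    "density_and_sparsity",
]


@dataclass(frozen=True)
class Graph:
    """Undirected simple binary graph.

    Attributes
    ----------
    node_labels:
        Ordered, unique labels; node ``i`` is ``node_labels[i]``.
    A:
        Symmetric ``n x n`` adjacency matrix with entries in {0, 1} and a
        zero diagonal.
    """

    node_labels: tuple
    A: np.ndarray

    def __post_init__(self):
        labels = tuple(str(x) for x in self.node_labels)
        object.__setattr__(self, "node_labels", labels)
        if len(set(labels)) != len(labels):
            raise InputError("node labels must be unique")
        A = np.asarray(self.A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise InputError("adjacency matrix must be square")
        if A.shape[0] != len(labels):
            raise InputError(
                f"adjacency is {A.shape[0]}x{A.shape[0]} but {len(labels)} labels given"
            )
        if not np.array_equal(A, A.T):
            raise InputError("adjacency matrix must be symmetric")
        if np.any(np.diag(A) != 0):
            raise InputError("self-loops are not allowed (diagonal must be zero)")
        if not np.isin(A, (0, 1)).all():
            raise InputError("adjacency entries must be 0 or 1")
        A = A.astype(np.int8, copy=True)
        A.setflags(write=False)
        object.__setattr__(self, "A", A)

    @property
    def n(self) -> int:
        """Node count."""
        return self.A.shape[0]

    @property
    def k(self) -> np.ndarray:
        """Degree vector, ``k_i = sum_j A_ij``."""
        return self.A.sum(axis=1).astype(np.int64)

    @property
    def m(self) -> int:
        """Total edge count, ``sum_i k_i / 2``."""
        return int(self.A.sum()) // 2

    def edges(self) -> list:
        """Edges as (i, j) index pairs with i < j."""
        iu, ju = np.nonzero(np.triu(self.A, k=1))
        return list(zip(iu.tolist(), ju.tolist()))

    def index_of(self, label: str) -> int:
        return self.node_labels.index(label)


@dataclass(frozen=True)
class SignVector:
    """Bipartition assignment: entries in {-1, +1}."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.int64)
        if v.ndim != 1 or not np.isin(v, (-1, 1)).all():
            raise InputError("sign vector entries must be -1 or +1")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class TernaryVector:
    """Ternary assignment: entries in {-1, 0, +1}; zeros mark gray nodes."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.int64)
        if v.ndim != 1 or not np.isin(v, (-1, 0, 1)).all():
            raise InputError("ternary vector entries must be -1, 0 or +1")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __len__(self):
        return len(self.values)


def build_graph(edges, node_labels) -> Graph:
    """Build a :class:`Graph` from labelled edges.

    Duplicate edges (in either orientation) collapse to a single edge with
    a logged warning.  Unknown endpoint labels and self-loops raise
    :class:`~graynet.errors.InputError`.
    """
    labels = [str(x) for x in node_labels]
    index = {lab: i for i, lab in enumerate(labels)}
    if len(index) != len(labels):
        raise InputError("node labels must be unique")
    n = len(labels)
    A = np.zeros((n, n), dtype=np.int8)
    n_dup = 0
    for a, b in edges:
        a, b = str(a), str(b)
        if a not in index:
            raise InputError(f"unknown endpoint label: {a!r}")
        if b not in index:
            raise InputError(f"unknown endpoint label: {b!r}")
        if a == b:
            raise InputError(f"self-loop on node {a!r} is not allowed")
        i, j = index[a], index[b]
        if A[i, j]:
            n_dup += 1
        A[i, j] = A[j, i] = 1
    if n_dup:
        logger.warning("collapsed %d duplicate edge(s)", n_dup)
    return Graph(tuple(labels), A)


def from_adjacency(A, node_labels=None) -> Graph:
    """Wrap an adjacency matrix as a :class:`Graph`, defaulting labels to v0..v{n-1}."""
    A = np.asarray(A)
    if node_labels is None:
        node_labels = [f"v{i}" for i in range(A.shape[0])]
    return Graph(tuple(node_labels), A)


def connected_components(g: Graph):
    """Connected components as node-index sets, sorted by smallest member.

    Singletons are included, so the sets partition ``range(g.n)``.
    """
    if g.n == 0:
        return []
    n_comp, labels = _scipy_components(csr_matrix(g.A), directed=False)
    comps = [set() for _ in range(n_comp)]
    for node, c in enumerate(labels):
        comps[c].add(node)
    return sorted(comps, key=min)


def density_and_sparsity(g: Graph):
    """Return ``(density, sparsity)``.

    density = m / (n(n-1)/2); sparsity = 1 - density.  Both are reported
    because "sparsity" is used with either meaning in the literature.
    """
    if g.n < 2:
        raise InputError("density requires at least 2 nodes")
    possible = g.n * (g.n - 1) // 2
    density = g.m / possible
    return density, 1.0 - density
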