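"""Undirected feature-interaction networks.

A :class:`Network` is the graph over model features (typically genes) from
which the pairwise penalty matrices are built.  It wraps a symmetric,
nonnegative, zero-diagonal adjacency matrix together with the feature
identifiers, and provides readers for the two plain-text formats common in
the field: tab-separated edge lists and SIF.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["Network", "read_edgelist", "read_sif", "scramble_network"]


class Network:
    """An undirected, weighted graph over ``p`` features.

    Parameters
    ----------
    node_ids : sequence of str
        Unique feature identifiers, one per node.
    adjacency : (p, p) array or sparse matrix
        Symmetric, nonnegative, zero-diagonal adjacency.  Entries are edge
        weights; 0/1 for unweighted graphs.
    """

    def __init__(self, node_ids: Sequence[str], adjacency) -> None:
        node_ids = [str(x) for x in node_ids]
        if len(set(node_ids)) != len(node_ids):
            raise ValueError("node_ids must be unique")
        A = sp.csr_matrix(adjacency, dtype=float)
        if A.shape[0] != A.shape[1] or A.shape[0] != len(node_ids):
            raise ValueError("adjacency shape does not match node_ids")
        if (abs(A - A.T) > 1e-12 * max(1.0, abs(A).max())).nnz > 0:
            raise ValueError("adjacency must be symmetric")
        if A.nnz and A.data.min() < 0:
            raise ValueError("adjacency must be nonnegative")
        if abs(A.diagonal()).max(initial=0.0) > 0:
            raise ValueError("adjacency must have a zero diagonal "
                             "(drop self-loops before constructing)")
        A.eliminate_zeros()
        self.node_ids = node_ids
        self.adjacency = A

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def degrees(self) -> np.ndarray:
        """Weighted node degrees (adjacency row sums)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.node_ids)}
        return np.array([pos[g] for g in ids], dtype=int)

    def subnetwork(self, ids: Sequence[str]) -> "Network":
        """Induced subgraph on ``ids`` (order follows ``ids``)."""
        idx = self.index_of(ids)
        A = self.adjacency[idx][:, idx]
        return Network([self.node_ids[i] for i in idx], A)

    def edge_array(self) -> np.ndarray:
        """Upper-triangle edges as an (m, 2) index array."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return np.column_stack([coo.row, coo.col])

    # ------------------------------------------------------------------
    @classmethod
    def from_edges(cls, edges, node_ids=None, weights=None) -> "Network":
        """Build from an iterable of (u, v) id pairs; duplicates collapse."""
        edges = list(edges)
        if node_ids is None:
            seen: dict[str, None] = {}
            for u, v in edges:
                seen.setdefault(str(u))
                seen.setdefault(str(v))
            node_ids = list(seen)
        pos = {str(g): i for i, g in enumerate(node_ids)}
        p = len(node_ids)
        if weights is None:
            weights = [1.0] * len(edges)
        n_self = 0
        d: dict[tuple[int, int], float] = {}  # duplicate edges collapse
        for (u, v), w in zip(edges, weights):
            i, j = pos[str(u)], pos[str(v)]
            if i == j:
                n_self += 1
                continue
            d[(min(i, j), max(i, j))] = float(w)
        if n_self:
            logger.warning("dropped %d self-loop(s)", n_self)
        rows = [k[0] for k in d] + [k[1] for k in d]
        cols = [k[1] for k in d] + [k[0] for k in d]
        vals = list(d.values()) * 2
        A = sp.coo_matrix((vals, (rows, cols)), shape=(p, p)).tocsr()
        return cls(node_ids, A)

    def to_edgelist(self, path, header=("source", "target", "weight")) -> None:
        A = sp.triu(self.adjacency, k=1).tocoo()
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for i, j, w in zip(A.row, A.col, A.data):
                fh.write(f"{self.node_ids[i]}\t{self.node_ids[j]}\t{w:.10g}\n")


def read_edgelist(path) -> Network:
    """Read a 2- or 3-column tab-separated edge list with a header line."""
    edges, weights = [], []
    with open(path) as fh:
        header = fh.readline()
        if header is None:
            raise ValueError("empty edge-list file")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed edge-list line: {line!r}")
            edges.append((parts[0], parts[1]))
            weights.append(float(parts[2]) if len(parts) > 2 else 1.0)
    return Network.from_edges(edges, weights=weights)


def read_sif(path) -> Network:
    """Read a SIF file (``node <TAB> relation <TAB> node``); the relation
    column is ignored and edges are unweighted."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            src, targets = parts[0], parts[2:]
            for t in targets:
                edges.append((src, t))
    return Network.from_edges(edges)


def scramble_network(net: Network, fraction: float, seed=None) -> Network:
    """Symmetrically permute a random fraction of adjacency rows/columns.

    ``ceil(fraction * p)`` node indices are chosen uniformly without
    replacement and a uniformly random permutation is applied to the rows
    and columns of the adjacency at those indices.  This corrupts the
    individual feature-feature relationships while preserving the global
    degree structure of the graph; ``fraction=0`` is the identity.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = net.n_nodes
    k = int(np.ceil(fraction * p))
    perm = np.arange(p)
    if k >= 2:
        chosen = rng.choice(p, size=k, replace=False)
        perm[chosen] = chosen[rng.permutation(k)]
    A = net.adjacency[perm][:, perm]
    return Network(list(net.node_ids), A)
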