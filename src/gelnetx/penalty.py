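"""Feature-pair penalty matrices.

The L2 term of the generalized elastic net is ``(lambda2/2) * w' P w`` for a
positive semi-definite matrix ``P`` expressing *dissimilarity* between
features.  This module builds the standard choices from an interaction
network:

* the (normalized) graph Laplacian, whose quadratic form
  ``w' L w = 1/2 * sum_ij A_ij (w_i - w_j)^2`` penalizes weight differences
  across edges;
* the diffusion penalty ``I - expm(-t L)``, which looks beyond immediate
  neighborhoods by running heat flow on the graph for time ``t``;
* the ridge/Laplacian blend ``I + beta L`` (the network-induced
  classification kernel regularizer);
* the Moore-Penrose pseudo-inverse of an arbitrary PSD kernel, turning any
  similarity kernel into a dissimilarity penalty.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .network import Network

__all__ = [
    "PenaltyMatrix",
    "build_laplacian",
    "build_diffusion_penalty",
    "build_nick_penalty",
    "pseudo_inverse_penalty",
    "identity_penalty",
]

_PROVENANCES = {
    "laplacian", "normalized_laplacian", "diffusion", "nick",
    "pseudo_inverse_kernel", "identity", "custom",
}


class PenaltyMatrix:
    """A symmetric positive semi-definite p-by-p feature-pair penalty.

    Stores either a dense ndarray or a scipy sparse matrix; all consumers
    see identical numerical behaviour regardless of storage.  Symmetry is
    checked at construction; positive semi-definiteness is checked by
    :meth:`validate` (constructors that are PSD by construction mark
    themselves so and skip the eigen-decomposition).
    """

    SYM_TOL = 1e-10
    PSD_TOL = 1e-8  # relative: min eigenvalue >= -PSD_TOL * ||P||

    def __init__(self, matrix, provenance: str = "custom",
                 node_ids=None, psd_known: bool = False) -> None:
        if provenance not in _PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        if sp.issparse(matrix):
            M = matrix.tocsr().astype(float)
            asym = abs(M - M.T)
            scale = max(1.0, abs(M).max())
            if asym.nnz and asym.max() > self.SYM_TOL * scale:
                raise ValueError("penalty matrix must be symmetric")
        else:
            M = np.asarray(matrix, dtype=float)
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError("penalty matrix must be square")
            scale = max(1.0, np.abs(M).max())
            if np.abs(M - M.T).max() > self.SYM_TOL * scale:
                raise ValueError("penalty matrix must be symmetric")
            M = 0.5 * (M + M.T)
        self.matrix = M
        self.provenance = provenance
        self.node_ids = list(node_ids) if node_ids is not None else None
        self._psd_known = bool(psd_known)
        if not psd_known:
            self.validate()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.matrix.shape

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return self.matrix.toarray()
        return np.array(self.matrix)

    def tocsr(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.matrix)

    def diagonal(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return self.matrix.diagonal()
        return np.diagonal(self.matrix).copy()

    def quad_form(self, w: np.ndarray) -> float:
        """``w' P w``."""
        return float(w @ (self.matrix @ w))

    def validate(self) -> "PenaltyMatrix":
        """Verify positive semi-definiteness; raise on violation.

        Violations are errors; eigenvalues are never clipped silently.
        """
        M = self.toarray()
        if M.size == 0:
            return self
        vals = np.linalg.eigvalsh(M)
        norm = max(np.abs(vals).max(), 1e-300)
        if vals[0] < -self.PSD_TOL * norm:
            raise ValueError(
                f"penalty matrix is not positive semi-definite "
                f"(min eigenvalue {vals[0]:.3e}, norm {norm:.3e})")
        self._psd_known = True
        return self

    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV with a node-id header row and first column."""
        ids = self.node_ids or [f"f{i}" for i in range(self.shape[0])]
        M = self.toarray()
        with open(path, "w") as fh:
            fh.write("\t".join(["#id"] + list(ids)) + "\n")
            for i, row in enumerate(M):
                fh.write(ids[i] + "\t" +
                         "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path, provenance: str = "custom") -> "PenaltyMatrix":
        with open(path) as fh:
            ids = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(v) for v in parts[1:]])
        return cls(np.array(rows), provenance=provenance, node_ids=ids)


# ----------------------------------------------------------------------
def _laplacian_parts(net: Network):
    A = net.adjacency
    deg = net.degrees
    return A, deg


def build_laplacian(net: Network, normalized: bool = False) -> PenaltyMatrix:
    """Graph Laplacian penalty ``L = Diag(deg) - A``.

    With ``normalized=True`` returns the symmetric normalized Laplacian,
    ``L~_ii = 1`` for every node with positive degree and
    ``L~_ij = -A_ij / sqrt(d_i d_j)`` off the diagonal.  Degree-0 nodes get
    diagonal 1 as well (identity convention), so that a fully disconnected
    node set has a Laplacian submatrix equal to the identity.
    """
    A, deg = _laplacian_parts(net)
    if not normalized:
        L = sp.diags(deg) - A
        return PenaltyMatrix(L.tocsr(), "laplacian",
                             node_ids=net.node_ids, psd_known=True)
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    Dinv = sp.diags(dinv)
    L = sp.eye(net.n_nodes, format="csr") - Dinv @ A @ Dinv
    # isolated nodes: eye already gives diagonal 1 (identity convention)
    return PenaltyMatrix(L.tocsr(), "normalized_laplacian",
                         node_ids=net.node_ids, psd_known=True)


def build_diffusion_penalty(net: Network, t: float = 0.1) -> PenaltyMatrix:
    """Diffusion penalty ``P = I - expm(-t L)`` (unnormalized Laplacian).

    The diffusion kernel ``D = expm(-t L)`` has all eigenvalues in (0, 1],
    so ``P`` is PSD.  ``t`` is the diffusion time: larger values spread
    "heat" further along the graph, making the penalty sensitive to longer
    paths.  ``t = 0`` gives the zero penalty.
    """
    if t < 0:
        raise ValueError("diffusion time t must be nonnegative")
    L = build_laplacian(net, normalized=False).toarray()
    # L is symmetric: use eigendecomposition rather than a general expm
    vals, vecs = np.linalg.eigh(L)
    D = (vecs * np.exp(-t * np.clip(vals, 0.0, None))) @ vecs.T
    P = np.eye(net.n_nodes) - D
    return PenaltyMatrix(P, "diffusion", node_ids=net.node_ids,
                         psd_known=True)


def build_nick_penalty(net: Network, beta: float) -> PenaltyMatrix:
    """Ridge/Laplacian blend ``P = I + beta L`` (strictly positive
    definite); ``beta = 0`` recovers the classical ridge penalty."""
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    L = build_laplacian(net, normalized=False).tocsr()
    P = sp.eye(net.n_nodes, format="csr") + beta * L
    return PenaltyMatrix(P.tocsr(), "nick", node_ids=net.node_ids,
                         psd_known=True)


def pseudo_inverse_penalty(kernel, node_ids=None,
                           rcond: float = 1e-10) -> PenaltyMatrix:
    """Moore-Penrose pseudo-inverse of a PSD kernel matrix.

    A kernel measures feature *similarity*; its pseudo-inverse is the
    matching dissimilarity penalty (e.g. the Laplacian is the pseudo-inverse
    of the graph's reproducing kernel, ``(L^+)^+ = L``).  Asymmetric or
    indefinite input is rejected.
    """
    if isinstance(kernel, PenaltyMatrix):
        node_ids = node_ids or kernel.node_ids
        kernel = kernel.toarray()
    K = np.asarray(kernel, dtype=float)
    scale = max(1.0, np.abs(K).max())
    if K.ndim != 2 or K.shape[0] != K.shape[1] or \
            np.abs(K - K.T).max() > 1e-10 * scale:
        raise ValueError("kernel must be a symmetric square matrix")
    vals, vecs = np.linalg.eigh(0.5 * (K + K.T))
    norm = max(np.abs(vals).max(), 1e-300)
    if vals[0] < -1e-8 * norm:
        raise ValueError("kernel must be positive semi-definite")
    inv = np.where(vals > rcond * norm, 1.0 / np.clip(vals, 1e-300, None), 0.0)
    P = (vecs * inv) @ vecs.T
    return PenaltyMatrix(P, "pseudo_inverse_kernel", node_ids=node_ids,
                         psd_known=True)


def identity_penalty(p: int, node_ids=None) -> PenaltyMatrix:
    """The identity penalty (classical elastic net L2 term)."""
    return PenaltyMatrix(sp.eye(p, format="csr"), "identity",
                         node_ids=node_ids, psd_known=True)
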