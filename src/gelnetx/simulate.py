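"""Synthetic benchmark generator: scale-free networks, planted pathways,
and expression data coupled (or not) to the network.

The generator reproduces a four-scenario study design.  A scale-free graph
over ``p`` features is drawn by preferential attachment; a connected
"pathway" covering a fixed fraction of nodes is selected by a random walk
and defines the true 0/1 weight vector.  Expression is sampled from a
multivariate normal ``X ~ N(0, S)`` where either (a) the precision matrix
``S^-1`` is a ridge-shifted copy of the graph adjacency, so that the
conditional-independence structure of the data matches the network
(Gaussian graphical model, "GGM" scenarios), or (b) ``S`` is a random
Wishart-style covariance with no relationship to the network ("Rand"
scenarios).  The noiseless response is ``y = X w``.  The learner is then
handed either the true network ("+") or a fully scrambled one ("-").
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import networkx as nx
import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .network import Network, scramble_network

__all__ = [
    "SimulationConfig", "SyntheticDataset",
    "generate_scale_free_graph", "sample_pathway_weights",
    "ggm_covariance", "random_covariance", "simulate_dataset",
    "SCENARIOS",
]

SCENARIOS = ("GGM+", "GGM-", "Rand+", "Rand-")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the reference design: 5000 features observed on 50
    samples, a random-walk pathway covering 10% of the nodes, preferential
    attachment with 2 edges per new node, precision ridge 0.1 and a
    noiseless response.
    """
    p: int = 5000
    n: int = 50
    pathway_fraction: float = 0.10
    attachment_m: int = 2
    ggm_ridge: float = 0.1
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.pathway_fraction < 1:
            raise ValueError("pathway_fraction must lie in (0, 1)")
        if self.p < self.attachment_m + 1:
            raise ValueError("p must exceed attachment_m")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    """One simulated regression problem plus its generating truth."""
    X: np.ndarray
    y: np.ndarray
    w_true: np.ndarray
    net_true: Network
    net_given: Network
    scenario: str
    seed: Optional[int]
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def pathway_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.w_true)


# ----------------------------------------------------------------------
def generate_scale_free_graph(p: int, attachment_m: int = 2,
                              seed=None) -> Network:
    """Connected scale-free graph via Barabasi-Albert preferential
    attachment (``attachment_m`` edges per newly added node)."""
    if p < attachment_m + 1:
        raise ValueError("p must be at least attachment_m + 1")
    seed_int = int(np.random.default_rng(seed).integers(2 ** 31))
    G = nx.barabasi_albert_graph(p, attachment_m, seed=seed_int)
    A = nx.to_scipy_sparse_array(G, nodelist=range(p), format="csr",
                                 dtype=float)
    return Network([f"g{i}" for i in range(p)], sp.csr_matrix(A))


def sample_pathway_weights(net: Network, pathway_fraction: float = 0.10,
                           seed=None, step_budget: Optional[int] = None
                           ) -> np.ndarray:
    """0/1 weight vector over a connected subgraph chosen by random walk.

    A simple random walk starts at a uniformly chosen node and collects
    distinct visited nodes until ``ceil(pathway_fraction * p)`` have been
    seen; those nodes get weight 1.  The collected set is connected by
    construction.  Raises if the step budget is exhausted (e.g. the walk
    is trapped in a small disconnected component).
    """
    rng = np.random.default_rng(seed)
    p = net.n_nodes
    target = int(np.ceil(pathway_fraction * p))
    if step_budget is None:
        step_budget = 1000 * p
    A = net.adjacency
    indptr, indices = A.indptr, A.indices
    node = int(rng.integers(p))
    visited = {node}
    steps = 0
    while len(visited) < target:
        nbrs = indices[indptr[node]:indptr[node + 1]]
        if nbrs.size == 0:
            raise RuntimeError("random walk stuck on an isolated node")
        node = int(nbrs[rng.integers(nbrs.size)])
        visited.add(node)
        steps += 1
        if steps > step_budget:
            raise RuntimeError(
                "random-walk step budget exhausted; is the graph connected?")
    w = np.zeros(p)
    w[list(visited)] = 1.0
    return w


def ggm_covariance(net: Network, delta: float = 0.1,
                   check_support: bool = False) -> np.ndarray:
    """Covariance whose precision matrix mirrors the graph structure.

    The precision is the ridge-shifted graph Laplacian
    ``Omega = Diag(deg) - A + delta I`` (positive definite for any
    ``delta > 0``) and the returned covariance is its inverse.  The
    off-diagonal support of ``S^-1`` equals the edge set of the graph
    exactly, and network neighbours come out positively partially
    correlated, so the sampled expression carries the graph's
    co-expression structure.  ``check_support=True`` verifies the support
    certificate numerically by re-inverting ``S``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    p = net.n_nodes
    A = net.adjacency.toarray()
    if p == 0:
        raise ValueError("empty network")
    omega = np.diag(A.sum(axis=1)) - A + delta * np.eye(p)
    try:
        cf = sla.cho_factor(omega)
        S = sla.cho_solve(cf, np.eye(p))
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise RuntimeError(f"precision matrix inversion failed: {err}")
    S = 0.5 * (S + S.T)
    if check_support:
        prec = np.linalg.inv(S)
        off = prec - np.diag(np.diag(prec))
        min_edge = net.adjacency.data.min() if net.adjacency.nnz else 1.0
        err = np.abs(off + A).max()
        if err > 0.5 * min_edge:
            raise RuntimeError(
                f"support certificate failed: max off-diagonal deviation "
                f"{err:.3e}")
    return S


def random_covariance(p: int, seed=None) -> np.ndarray:
    """Wishart-style random covariance ``G G'/p + 1e-3 I`` (positive
    definite, statistically independent of any network)."""
    if p < 1:
        raise ValueError("p must be positive")
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((p, p))
    return G @ G.T / p + 1e-3 * np.eye(p)


# ----------------------------------------------------------------------
def simulate_dataset(cfg: SimulationConfig,
                     scenario: str = "GGM+") -> SyntheticDataset:
    """Draw one dataset under the given scenario (GGM+/-, Rand+/-)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    ss = np.random.SeedSequence(cfg.seed)
    s_graph, s_walk, s_cov, s_x, s_scr = [
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(5)]
    net = generate_scale_free_graph(cfg.p, cfg.attachment_m, seed=s_graph)
    w_true = sample_pathway_weights(net, cfg.pathway_fraction, seed=s_walk)
    if scenario.startswith("GGM"):
        S = ggm_covariance(net, cfg.ggm_ridge)
    else:
        S = random_covariance(cfg.p, seed=s_cov)
    chol = np.linalg.cholesky(S)
    rng = np.random.default_rng(s_x)
    X = rng.standard_normal((cfg.n, cfg.p)) @ chol.T
    y = X @ w_true
    if cfg.noise_sd > 0:
        y = y + cfg.noise_sd * rng.standard_normal(cfg.n)
    if scenario.endswith("+"):
        net_given = net
    else:
        net_given = scramble_network(net, 1.0, seed=s_scr)
    return SyntheticDataset(X=X, y=y, w_true=w_true, net_true=net,
                            net_given=net_given, scenario=scenario,
                            seed=cfg.seed, config=cfg)
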