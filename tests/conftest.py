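"""Shared fixtures.

The scramble battery is the heavy shared computation: 10 GGM datasets at
p=500/n=50 with the full meta-parameter grid, compared at scramble
fractions {0, 0.1, 0.2, 1.0}.  It is computed once per session and reused
by the robustness, positive-control and relevance tests.
"""

import numpy as np
import pytest
import scipy.sparse as sp

from gelnetx import Network, SimulationConfig
from gelnetx.evaluate import scramble_sweep

BATTERY_SEED = 2024
BATTERY_FRACTIONS = (0.0, 0.1, 0.2, 1.0)
BATTERY_RUNS = 10
BATTERY_PAIRS = 100


@pytest.fixture(scope="session")
def ggm_battery():
    """(table, reports): matched-sparsity comparisons on 10 GGM datasets
    at four scramble fractions of the true network."""
    cfg = SimulationConfig(p=500, n=50)
    return scramble_sweep(cfg, BATTERY_FRACTIONS, BATTERY_RUNS,
                          seed=BATTERY_SEED, n_pairs=BATTERY_PAIRS,
                          return_reports=True)


@pytest.fixture(scope="session")
def star_network():
    """Star graph: node 0 is the hub, nodes 1..6 are leaves."""
    edges = [("hub", f"leaf{i}") for i in range(1, 7)]
    return Network.from_edges(edges,
                              node_ids=["hub"] + [f"leaf{i}"
                                                  for i in range(1, 7)])


def random_network(p, rng, edge_prob=0.1):
    """Symmetric 0/1 adjacency with zero diagonal."""
    A = (rng.random((p, p)) < edge_prob).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    return Network([f"g{i}" for i in range(p)], sp.csr_matrix(A))
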