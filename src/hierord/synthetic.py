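"""Planted-hierarchy random graphs for parameter-recovery testing.

The generator encodes the locality assumption behind pseudo hierarchical
distances: when information is processed in stages, direct links between
nodes far apart in the hierarchy are rare.  Nodes receive known integer
levels in {0..K} and each ordered pair (u, v) gets a directed edge
independently with probability

    p(u, v) = p0 * exp(-beta * |h(u) - h(v)|),

so the edge rate decays exponentially with level distance.  beta = 0
recovers a uniform Erdos-Renyi digraph; larger beta concentrates edges
on same-level and adjacent-level pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hierord.errors import ConnectivityError
from hierord.graph_io import DirectedGraph, LevelTable

__all__ = ["PlantedHierarchy", "generate_planted_hierarchy", "planted_levels"]


@dataclass(frozen=True)
class PlantedHierarchy:
    """A synthetic directed graph together with its true node levels."""

    graph: DirectedGraph
    true_levels: LevelTable
    n: int
    K: int
    p0: float
    beta: float
    seed: int


def planted_levels(n: int, K: int) -> np.ndarray:
    """Deterministic round-robin level assignment over {0..K}.

    Node i gets level i mod (K+1), spreading nodes as evenly as possible
    across levels; only the edges are random in the generator.
    """
    return np.arange(n) % (K + 1)


def _weakly_connected(W: np.ndarray) -> bool:
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(W > 0, directed=True, connection="weak")
    return n_comp == 1


def generate_planted_hierarchy(
    n: int,
    K: int,
    p0: float,
    beta: float,
    seed: int,
    max_attempts: int = 100,
    require_connected: bool = True,
) -> PlantedHierarchy:
    """Sample a planted-hierarchy digraph with level-distance edge decay.

    Parameters
    ----------
    n : number of nodes (>= 2)
    K : maximum hierarchy level (>= 1); levels are {0..K}
    p0 : base edge probability for a same-level ordered pair, in (0, 1]
    beta : exponential decay rate per unit of level distance (>= 0)
    seed : RNG seed; equal seeds give identical output
    max_attempts : resampling budget to obtain a weakly connected graph
    require_connected : set False to keep the first draw even if it is
        disconnected (e.g. extreme beta, where cross-level edges vanish
        and connectivity is unattainable by construction)

    Raises
    ------
    ValueError : invalid parameters
    ConnectivityError : no weakly connected draw within ``max_attempts``
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if not 0.0 < p0 <= 1.0:
        raise ValueError(f"p0 must be in (0, 1], got {p0}")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")

    levels = planted_levels(n, K)
    dist = np.abs(levels[:, None] - levels[None, :])
    prob = p0 * np.exp(-beta * dist)
    np.fill_diagonal(prob, 0.0)  # no self-loops

    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        W = (rng.random((n, n)) < prob).astype(float)
        if not require_connected or _weakly_connected(W):
            break
    else:
        raise ConnectivityError(
            f"no weakly connected graph in {max_attempts} attempts "
            f"(n={n}, K={K}, p0={p0}, beta={beta}); raise p0 or lower beta"
        )

    width = len(str(n - 1))
    labels = tuple(f"N{i:0{width}d}" for i in range(n))
    graph = DirectedGraph(labels=labels, W=W)
    true_levels = LevelTable(entries={lab: float(h) for lab, h in zip(labels, levels)})
    return PlantedHierarchy(
        graph=graph, true_levels=true_levels, n=n, K=K, p0=p0, beta=beta, seed=seed
    )
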