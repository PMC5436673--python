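import numpy as np
import pytest

from hierord import generate_planted_hierarchy, spectral
from hierord.graph_io import DirectedGraph


@pytest.fixture
def cycle3() -> DirectedGraph:
    """Directed 3-cycle A->B->C->A."""
    W = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    return DirectedGraph(labels=("A", "B", "C"), W=W)


@pytest.fixture
def path3() -> DirectedGraph:
    """Undirected path A-B-C (symmetric adjacency)."""
    W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return DirectedGraph(labels=("A", "B", "C"), W=W)


@pytest.fixture
def planted40():
    """Planted hierarchy at the study conditions (n=40, K=9, p0=0.6, beta=1.5)."""
    return generate_planted_hierarchy(n=40, K=9, p0=0.6, beta=1.5, seed=0)


def full_embedding(g: DirectedGraph, k: int, eta: float | None = None):
    """Helper: run the whole spectral stage on a graph."""
    eta_used = spectral.default_eta(g) if eta is None else eta
    tm = spectral.transition_matrix(g, eta=eta_used)
    se = spectral.directed_laplacian(tm, spectral.perron_vector(tm))
    return spectral.embed(se, k)
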