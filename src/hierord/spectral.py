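"""Spectral embedding of a directed graph via the normalized directed Laplacian.

The embedding follows the directed-graph Laplacian of Chung: form the
random-walk transition matrix P = D^-1 W (rows with zero out-degree are
replaced by the uniform row), optionally mix in teleportation
P' = eta*P + (1-eta)/n so the chain is irreducible, find the Perron
vector psi (the stationary distribution, i.e. the positive left
eigenvector of P' at eigenvalue 1), and build the symmetric operator

    L_d = I - (Psi^{1/2} P' Psi^{-1/2} + Psi^{-1/2} P'^T Psi^{1/2}) / 2,

where Psi = diag(psi).  Its eigenvalues lie in [0, 2] with lambda_1 = 0
and eigenvector psi^{1/2}.  The first k eigenvectors, row-normalized to
the unit sphere, are the node representative vectors.  Gaps between
consecutive eigenvalues guide the choice of the embedding dimension k
and the number of hierarchy levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from hierord.errors import SpectralError
from hierord.graph_io import DirectedGraph

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionMatrix",
    "PerronResult",
    "SpectralEmbedding",
    "SpectralGaps",
    "transition_matrix",
    "perron_vector",
    "directed_laplacian",
    "embed",
    "spectral_gaps",
    "suggest_parameters",
    "is_strongly_connected",
    "default_eta",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic random-walk matrix with optional teleportation.

    ``P`` is the teleported matrix eta*D^-1 W + (1-eta)/n actually used
    downstream; ``eta = 1`` means the pure random walk.
    """

    P: np.ndarray
    eta: float

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class PerronResult:
    """Stationary distribution of the walk: psi > 0, sum(psi) = 1."""

    psi: np.ndarray
    rho: float


@dataclass(frozen=True)
class SpectralEmbedding:
    """Eigendecomposition of L_d and the derived node embedding.

    ``lambdas`` ascend; ``vectors`` columns are the matching
    eigenvectors with a deterministic sign (first component of
    magnitude > 1e-12 is positive).  After :func:`embed`, ``Y`` holds
    the first k eigenvectors and ``Z`` the row-normalized embedding
    whose row i is the representative vector of node i.
    """

    L_d: np.ndarray
    lambdas: np.ndarray
    vectors: np.ndarray
    k: int | None = None
    Y: np.ndarray | None = None
    Z: np.ndarray | None = None


@dataclass(frozen=True)
class SpectralGaps:
    """Consecutive eigenvalue differences gamma_i = lambda_{i+1} - lambda_i."""

    gaps: np.ndarray


def is_strongly_connected(g: DirectedGraph) -> bool:
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(g.W > 0, directed=True, connection="strong")
    return n_comp == 1


def default_eta(g: DirectedGraph) -> float:
    """eta = 1 for strongly connected graphs, else 0.99 teleportation.

    The directed Laplacian needs a unique positive Perron vector, which
    pure random walks only guarantee on strongly connected graphs.
    """
    return 1.0 if is_strongly_connected(g) else 0.99


def transition_matrix(g: DirectedGraph, eta: float = 1.0) -> TransitionMatrix:
    """Build the (teleported) random-walk transition matrix of a graph.

    Rows with zero out-degree become the uniform row before teleportation.
    """
    if not 0.0 < eta <= 1.0:
        raise ValueError(f"eta must be in (0, 1], got {eta}")
    W = g.W
    n = g.n
    d = W.sum(axis=1)
    P = np.empty_like(W, dtype=float)
    dangling = d <= 0
    P[~dangling] = W[~dangling] / d[~dangling, None]
    P[dangling] = 1.0 / n
    if eta < 1.0:
        P = eta * P + (1.0 - eta) / n
    return TransitionMatrix(P=P, eta=eta)


def perron_vector(tm: TransitionMatrix, tol: float = 1e-10) -> PerronResult:
    """Left eigenvector of P at the largest eigenvalue, normalized to sum 1.

    Uses a dense eigendecomposition of P^T.  For a row-stochastic
    irreducible P the eigenvalue is 1 and psi is the unique stationary
    distribution.  Entries below ``-tol`` (after sign normalization)
    indicate a reducible chain; lower eta to restore irreducibility.
    """
    P = tm.P
    vals, vecs = scipy.linalg.eig(P.T)
    i = int(np.argmax(vals.real))
    rho = float(vals[i].real)
    psi = vecs[:, i].real
    s = psi.sum()
    if abs(s) < tol:
        raise SpectralError("Perron eigenvector sums to ~0; graph may be reducible")
    psi = psi / s
    if np.min(psi) < -tol:
        raise SpectralError(
            f"Perron vector has non-positive entries (min={np.min(psi):.3e}); "
            "the transition matrix is reducible — lower eta below 1"
        )
    psi = np.maximum(psi, tol)  # clamp tiny negatives from roundoff
    psi = psi / psi.sum()
    return PerronResult(psi=psi, rho=rho)


def _fix_signs(vectors: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Make the first component of magnitude > tol positive, per column."""
    V = vectors.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.flatnonzero(np.abs(col) > tol)
        if nz.size and col[nz[0]] < 0:
            V[:, j] = -col
    return V


def directed_laplacian(
    tm: TransitionMatrix, perron: PerronResult, psi_tol: float = 1e-12
) -> SpectralEmbedding:
    """Normalized directed Laplacian and its full eigendecomposition.

    L_d = I - (Psi^{1/2} P Psi^{-1/2} + Psi^{-1/2} P^T Psi^{1/2}) / 2
    with Psi = diag(psi).  L_d is symmetrized against roundoff and
    decomposed densely; eigenvalues ascend, eigenvector signs are fixed
    deterministically.
    """
    psi = perron.psi
    if np.min(psi) <= psi_tol:
        raise SpectralError(
            f"Perron vector entry below positivity tolerance ({np.min(psi):.3e})"
        )
    sq = np.sqrt(psi)
    M = (sq[:, None] * tm.P / sq[None, :] + tm.P.T * sq[None, :] / sq[:, None]) / 2.0
    L = np.eye(tm.n) - M
    L = (L + L.T) / 2.0
    lambdas, vectors = scipy.linalg.eigh(L)
    vectors = _fix_signs(vectors)
    return SpectralEmbedding(L_d=L, lambdas=lambdas, vectors=vectors)


def embed(
    se: SpectralEmbedding, k: int, drop_first: bool = False, norm_tol: float = 1e-12
) -> SpectralEmbedding:
    """Populate the k-dimensional row-normalized embedding Z.

    Y takes the first k eigenvectors including the trivial first one
    (``drop_first=True`` starts at the second instead); each row of Y is
    then scaled to unit Euclidean norm so nodes live on the k-sphere.
    """
    n = se.L_d.shape[0]
    if not 1 <= k <= n - (1 if drop_first else 0):
        raise ValueError(f"k={k} out of range for n={n} (drop_first={drop_first})")
    lo = 1 if drop_first else 0
    Y = se.vectors[:, lo : lo + k]
    norms = np.linalg.norm(Y, axis=1)
    if np.any(norms < norm_tol):
        bad = int(np.argmin(norms))
        raise SpectralError(
            f"embedding row {bad} has norm {norms[bad]:.3e} < {norm_tol}; "
            "k is too small or the graph is degenerate"
        )
    Z = Y / norms[:, None]
    return SpectralEmbedding(
        L_d=se.L_d, lambdas=se.lambdas, vectors=se.vectors, k=k, Y=Y, Z=Z
    )


def spectral_gaps(se: SpectralEmbedding) -> SpectralGaps:
    """Magnitudes of consecutive eigenvalue differences (n-1 gaps)."""
    return SpectralGaps(gaps=np.diff(se.lambdas))


def suggest_parameters(
    sg: SpectralGaps,
    c: float = 2.0,
    default_k: int = 4,
    similar_ratio: float = 3.0,
) -> tuple[int, int, str]:
    """Heuristic (k, K) suggestion from the spectral-gap profile.

    A leading gap counts as "large" while it exceeds ``c`` times the
    median of the gaps that follow it; k is the number of such leading
    large gaps (falling back to ``default_k`` when none stand out).  The
    run of "relatively similar" gaps that follows — consecutive gaps
    within a factor ``similar_ratio`` of the run's first gap — extends
    the level count, giving total levels = large + run and K = total - 1.

    Both values are suggestions for a human in the loop: the returned
    justification string spells out the reasoning and callers may
    override either number.
    """
    gaps = np.asarray(sg.gaps, dtype=float)
    if gaps.size < 3:
        raise ValueError(f"need at least 3 spectral gaps, got {gaps.size}")

    n_large = 0
    while n_large < gaps.size - 1:
        rest = gaps[n_large + 1 :]
        if gaps[n_large] > c * float(np.median(rest)):
            n_large += 1
        else:
            break

    if n_large == 0:
        logger.warning(
            "no leading spectral gap stands out (threshold %gx median); "
            "falling back to default k=%d",
            c,
            default_k,
        )
        k = default_k
        reason = (
            f"no leading gap exceeds {c}x the median of the remaining gaps; "
            f"fell back to default k={default_k}"
        )
    else:
        k = n_large
        reason = f"{n_large} leading gap(s) exceed {c}x the median of the gaps after them"

    run = 0
    start = n_large
    if start < gaps.size:
        ref = gaps[start]
        for gv in gaps[start:]:
            lo, hi = ref / similar_ratio, ref * similar_ratio
            if gv > 0 and lo <= gv <= hi:
                run += 1
            else:
                break
    total_levels = max(n_large + run, 2)
    K = total_levels - 1
    reason += (
        f"; {run} similar gap(s) follow, suggesting {total_levels} levels (K={K})"
    )
    return k, K, reason
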