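"""Pseudo hierarchical distances and anchored level assignment.

From the row-normalized embedding rows f(u_i) we compute the regularized
Tanimoto similarity

    s(u_i, u_j) = f_i . f_j / (||f_i - f_j||^2 + f_i . f_j + eps),

with eps = 1/delta and delta = K/2, and the pseudo hierarchical distance

    mu(u_i, u_j) = delta - s(u_i, u_j),

an estimate of the absolute level difference |h(u_i) - h(u_j)|.  Levels
are then found by minimizing

    sum_{i<j} (|h(u_i) - h(u_j)| - mu(u_i, u_j))^2

over h in [0, K]^n with a few anchored nodes held at fixed levels.  The
objective is nonconvex, so the minimizer runs many seeded random
restarts of a smoothed box-constrained quasi-Newton solve and averages
the restarts that land within a tolerance of the best local minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from hierord.errors import AnchorError, OptimizationError
from hierord.graph_io import AnchorSet

__all__ = [
    "DistanceModel",
    "HierarchyResult",
    "RestartRecord",
    "similarity",
    "pseudo_distance",
    "objective",
    "minimize_levels",
    "discretize",
]


@dataclass(frozen=True)
class DistanceModel:
    """Pairwise similarities and pseudo hierarchical distances.

    delta = K/2 centers the distance scale; eps = 1/delta bounds the
    similarity.  For unit-norm embedding rows s lies in
    [-1/(3+eps), 1/(1+eps)], so every mu = delta - s is strictly inside
    (0, K).
    """

    K: int
    S: np.ndarray
    mu: np.ndarray | None = None

    @property
    def delta(self) -> float:
        return self.K / 2.0

    @property
    def epsilon(self) -> float:
        return 2.0 / self.K  # 1/delta

    @property
    def n(self) -> int:
        return self.S.shape[0]


@dataclass(frozen=True)
class RestartRecord:
    seed: int
    objective: float
    h: np.ndarray
    converged: bool


@dataclass(frozen=True)
class HierarchyResult:
    """Continuous and discrete hierarchy levels with restart provenance."""

    h: np.ndarray
    levels: np.ndarray
    objective: float
    restarts: tuple[RestartRecord, ...]
    anchors: AnchorSet
    K: int
    kept: int = 0

    @property
    def best_objective(self) -> float:
        return min(r.objective for r in self.restarts)


def similarity(Z: np.ndarray, K: int, denom_tol: float = 1e-12) -> DistanceModel:
    """Regularized Tanimoto similarity matrix of unit-norm embedding rows.

    For unit rows ||f_i - f_j||^2 = 2 - 2 f_i.f_j, so the denominator
    reduces to 2 - f_i.f_j + eps, bounded away from zero for eps > 0.
    The diagonal is computed by the same formula (s_ii = 1/(1+eps)).
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    Z = np.asarray(Z, dtype=float)
    eps = 2.0 / K
    G = Z @ Z.T
    sq = np.sum(Z * Z, axis=1)
    dist2 = sq[:, None] + sq[None, :] - 2.0 * G
    denom = dist2 + G + eps
    if np.any(np.abs(denom) < denom_tol):
        raise FloatingPointError("similarity denominator underflow")
    S = G / denom
    S = (S + S.T) / 2.0
    return DistanceModel(K=K, S=S)


def pseudo_distance(dm: DistanceModel) -> DistanceModel:
    """mu = delta - S entrywise; symmetric with entries inside (0, K)."""
    mu = dm.delta - dm.S
    return DistanceModel(K=dm.K, S=dm.S, mu=mu)


def objective(h: np.ndarray, dm: DistanceModel) -> float:
    """Sum over unordered pairs i<j of (|h_i - h_j| - mu_ij)^2."""
    if dm.mu is None:
        raise ValueError("DistanceModel.mu not populated; call pseudo_distance first")
    h = np.asarray(h, dtype=float)
    z = np.abs(h[:, None] - h[None, :])
    r = z - dm.mu
    iu = np.triu_indices(dm.n, k=1)
    return float(np.sum(r[iu] ** 2))


def _smoothed_value_and_grad(
    h: np.ndarray, mu: np.ndarray, tau: float
) -> tuple[float, np.ndarray]:
    """Objective with |x| smoothed as sqrt(x^2 + tau^2), and its gradient."""
    diff = h[:, None] - h[None, :]
    z = np.sqrt(diff * diff + tau * tau)
    r = z - mu
    np.fill_diagonal(r, 0.0)
    val = 0.5 * float(np.sum(r * r))  # full matrix = 2x the i<j sum
    # d/dh_i of the i<j sum: sum_j 2 r_ij diff_ij / z_ij; the full-matrix
    # half-sum has the identical gradient.
    g = 2.0 * np.sum(r * diff / z, axis=1)
    return val, g


def _tau_schedule(K: float, tau: float) -> list[float]:
    """Graduated smoothing schedule from coarse (K/4) down to ``tau``.

    Each restart solves a sequence of box-constrained problems with the
    smoothing width shrinking tenfold per step; the coarse early solves
    navigate between the kinks of |x| that trap a single solve at the
    final tau.
    """
    taus: list[float] = []
    t = K / 4.0
    while t > 10.0 * tau:
        taus.append(t)
        t /= 10.0
    taus.append(tau)
    return taus


def minimize_levels(
    dm: DistanceModel,
    anchors: AnchorSet,
    labels: tuple[str, ...] | list[str],
    restarts: int = 50,
    seed: int = 0,
    tau: float = 1e-6,
    keep_frac: float = 0.05,
) -> HierarchyResult:
    """Anchored multi-restart minimization of the hierarchical-distance error.

    Anchored coordinates are removed from the optimization (hard equality
    constraints); free coordinates start uniformly at random in [0, K]
    per restart, with restart r seeded ``seed + r``.  Each restart
    minimizes the smoothed objective with L-BFGS-B under the box [0, K],
    following a continuation schedule in the smoothing width
    (coarse-to-fine down to ``tau``) so the solver does not stall on the
    kinks of |x|.  The
    returned h is the coordinate-wise mean over the restarts whose exact
    (unsmoothed) objective is within ``keep_frac`` of the best one,
    clipped back to [0, K] with anchors re-imposed; the reported
    objective is the exact objective at that averaged h.

    Parameters
    ----------
    dm : distance model with mu populated
    anchors : labels with fixed levels (at least one required)
    labels : node labels aligned with the rows of dm.mu
    restarts : number of random restarts (>= 1)
    seed : base RNG seed; restart r uses seed + r
    tau : final smoothing half-width for |x| ~ sqrt(x^2 + tau^2)
    keep_frac : restarts within (1 + keep_frac) * best objective are averaged
    """
    if dm.mu is None:
        raise ValueError("DistanceModel.mu not populated; call pseudo_distance first")
    if restarts < 1:
        raise ValueError(f"restarts must be >= 1, got {restarts}")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    labels = tuple(labels)
    n = dm.n
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for a {n}-node distance model")
    if not anchors.entries:
        raise AnchorError("anchor set is empty; at least one anchor is required")
    K = float(dm.K)

    anchor_idx: dict[int, float] = {}
    for lab, lev in anchors.entries.items():
        if lab not in labels:
            from hierord.errors import UnknownLabelError

            raise UnknownLabelError(f"anchored label {lab!r} not among the nodes")
        if not 0.0 <= float(lev) <= K:
            raise AnchorError(f"anchor {lab!r}={lev} outside [0, {K}]")
        anchor_idx[labels.index(lab)] = float(lev)

    free = np.array([i for i in range(n) if i not in anchor_idx], dtype=int)
    base = np.zeros(n)
    for i, lev in anchor_idx.items():
        base[i] = lev

    mu = dm.mu
    taus = _tau_schedule(K, tau)
    records: list[RestartRecord] = []
    for r in range(restarts):
        rseed = seed + r
        rng = np.random.default_rng(rseed)
        h = base.copy()
        if free.size:
            h[free] = rng.uniform(0.0, K, size=free.size)
            converged = True
            for t in taus:

                def fun(x: np.ndarray, _t: float = t) -> tuple[float, np.ndarray]:
                    hh = base.copy()
                    hh[free] = x
                    val, g = _smoothed_value_and_grad(hh, mu, _t)
                    return val, g[free]

                res = _scipy_minimize(
                    fun,
                    h[free],
                    jac=True,
                    method="L-BFGS-B",
                    bounds=[(0.0, K)] * free.size,
                )
                h[free] = np.clip(res.x, 0.0, K)
            converged = bool(res.success)
        else:
            converged = True
        records.append(
            RestartRecord(seed=rseed, objective=objective(h, dm), h=h, converged=converged)
        )

    ok = [rec for rec in records if np.isfinite(rec.objective)]
    if not ok:
        raise OptimizationError("all restarts failed to produce a finite objective")
    best = min(rec.objective for rec in ok)
    kept = [rec for rec in ok if rec.objective <= (1.0 + keep_frac) * best]
    h_mean = np.mean([rec.h for rec in kept], axis=0)
    h_mean = np.clip(h_mean, 0.0, K)
    for i, lev in anchor_idx.items():
        h_mean[i] = lev
    levels = discretize(h_mean, dm.K)
    for i, lev in anchor_idx.items():
        if float(lev).is_integer():
            levels[i] = int(lev)
    return HierarchyResult(
        h=h_mean,
        levels=levels,
        objective=objective(h_mean, dm),
        restarts=tuple(records),
        anchors=anchors,
        K=dm.K,
        kept=len(kept),
    )


def discretize(h: np.ndarray, K: int) -> np.ndarray:
    """Round half-up to the nearest integer, then clip to {0..K}."""
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("levels contain non-finite values")
    return np.clip(np.floor(h + 0.5), 0, K).astype(int)
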