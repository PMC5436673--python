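"""Scoring a computed hierarchy against a reference level table.

Three measures, all with population (1/n) denominators:

    PCC  = sum_i (x_i - m)(x~_i - m~) / sqrt(sum (x_i - m)^2 sum (x~_i - m~)^2)
    MAE  = (1/n) sum_i |x_i - x~_i|
    RMSE = sqrt((1/n) sum_i (x_i - x~_i)^2)

where x is the reference, x~ the computed levels, and m, m~ their means.
PCC is undefined (reported as None, not a number) when either vector is
constant over the compared nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from hierord.graph_io import DirectedGraph, LevelTable

logger = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "evaluate", "anchored_pair_fraction"]


@dataclass(frozen=True)
class EvaluationReport:
    """PCC/MAE/RMSE of computed vs reference levels on their shared nodes."""

    pcc: float | None
    mae: float
    rmse: float
    n: int
    labels: tuple[str, ...]
    x: np.ndarray
    x_tilde: np.ndarray

    @property
    def pcc_defined(self) -> bool:
        return self.pcc is not None

    def to_dict(self) -> dict:
        return {
            "pcc": self.pcc,
            "mae": self.mae,
            "rmse": self.rmse,
            "n": self.n,
        }


def evaluate(reference: LevelTable, computed: LevelTable) -> EvaluationReport:
    """Score computed levels against a reference, aligned by node label.

    Evaluation is restricted to the label intersection (logged when the
    two tables do not cover identical nodes); at least two shared nodes
    are required.
    """
    shared = [lab for lab in reference.entries if lab in computed.entries]
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} shared node(s) between reference and computed levels"
        )
    if len(shared) != len(reference.entries) or len(shared) != len(computed.entries):
        logger.info(
            "label sets differ; evaluating on the %d shared node(s)", len(shared)
        )
    x = reference.as_array(shared)
    xt = computed.as_array(shared)
    n = len(shared)
    err = x - xt
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    dx = x - x.mean()
    dxt = xt - xt.mean()
    sx = float(np.sum(dx**2))
    sxt = float(np.sum(dxt**2))
    if sx <= 0.0 or sxt <= 0.0:
        pcc: float | None = None
        logger.info("a level vector is constant on the shared nodes; PCC undefined")
    else:
        pcc = float(np.sum(dx * dxt) / np.sqrt(sx * sxt))
    return EvaluationReport(
        pcc=pcc, mae=mae, rmse=rmse, n=n, labels=tuple(shared), x=x, x_tilde=xt
    )


def anchored_pair_fraction(g: DirectedGraph, anchor_labels: list[str] | tuple[str, ...]) -> float:
    """Fraction of connected node pairs incident to at least one anchor.

    Anchoring a node fixes its hierarchical relationship to every area
    it connects with, so this fraction measures how much of the full
    pairwise hierarchical information the anchors supply.  Connected
    pairs are unordered pairs linked in at least one direction.
    """
    idx = [g.index(lab) for lab in anchor_labels]
    A = g.W > 0
    np.fill_diagonal(A, False)
    sym = np.triu(A | A.T, k=1)
    total = int(sym.sum())
    if total == 0:
        raise ValueError("graph has no connected pairs")
    mask = np.zeros(g.n, dtype=bool)
    mask[idx] = True
    touched = sym & (mask[:, None] | mask[None, :])
    return float(touched.sum()) / total
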