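"""End-to-end hierarchy-ordering runs with config capture and reporting.

``RunConfig`` holds every tunable of the pipeline and round-trips
through JSON, so a run report embeds everything needed to reproduce the
run exactly.  ``run_pipeline`` executes: load graph -> transition
matrix/Perron vector/directed Laplacian -> k-dimensional embedding ->
similarity and pseudo distances with K -> anchored multi-restart
minimization -> discretization, and optionally scores the result
against a reference level table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from hierord import graph_io, hierarchy, spectral
from hierord.errors import ConfigError
from hierord.evaluation import EvaluationReport, evaluate
from hierord.graph_io import AnchorSet, DirectedGraph, LevelTable

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_pipeline_on_graph"]


@dataclass
class RunConfig:
    """Fully resolved parameters of one hierarchy-ordering run."""

    graph: str = ""
    graph_format: str = "matrix"
    anchors: dict[str, float] = field(default_factory=dict)
    anchors_file: str | None = None
    reference: str | None = None
    k: int = 4
    K: int = 9
    eta: float | None = None  # None -> 1 if strongly connected else 0.99
    drop_first: bool = False
    restarts: int = 50
    seed: int = 0
    tau: float = 1e-6
    keep_frac: float = 0.05

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def validate(self) -> None:
        if not self.graph:
            raise ConfigError("config field 'graph' is required")
        if not Path(self.graph).exists():
            raise ConfigError(f"config field 'graph': file not found: {self.graph}")
        if self.anchors_file is not None and not Path(self.anchors_file).exists():
            raise ConfigError(
                f"config field 'anchors_file': file not found: {self.anchors_file}"
            )
        if not self.anchors and self.anchors_file is None:
            raise ConfigError("config requires 'anchors' or 'anchors_file'")
        if self.reference is not None and not Path(self.reference).exists():
            raise ConfigError(
                f"config field 'reference': file not found: {self.reference}"
            )
        if self.k < 1:
            raise ConfigError(f"config field 'k' must be >= 1, got {self.k}")
        if self.K < 1:
            raise ConfigError(f"config field 'K' must be >= 1, got {self.K}")
        if self.restarts < 1:
            raise ConfigError(f"config field 'restarts' must be >= 1")


@dataclass(frozen=True)
class PipelineResult:
    """Everything a run produced, plus the resolved config and timings."""

    config: RunConfig
    graph: DirectedGraph
    embedding: spectral.SpectralEmbedding
    gaps: np.ndarray
    hierarchy: hierarchy.HierarchyResult
    evaluation: EvaluationReport | None
    timings: dict[str, float]
    eta_used: float = 1.0

    @property
    def levels_table(self) -> LevelTable:
        return LevelTable(
            entries={
                lab: float(lv)
                for lab, lv in zip(self.graph.labels, self.hierarchy.levels)
            }
        )

    @property
    def continuous_table(self) -> LevelTable:
        return LevelTable(
            entries={
                lab: float(h) for lab, h in zip(self.graph.labels, self.hierarchy.h)
            }
        )

    def report(self) -> dict:
        rep = {
            "config": json.loads(self.config.to_json()),
            "eta_used": self.eta_used,
            "eigenvalues": [float(x) for x in self.embedding.lambdas],
            "spectral_gaps": [float(x) for x in self.gaps],
            "objective": self.hierarchy.objective,
            "best_restart_objective": self.hierarchy.best_objective,
            "restarts_kept": self.hierarchy.kept,
            "per_restart_objectives": [
                r.objective for r in self.hierarchy.restarts
            ],
            "timings_sec": self.timings,
        }
        if self.evaluation is not None:
            rep["evaluation"] = self.evaluation.to_dict()
        return rep


def run_pipeline_on_graph(
    g: DirectedGraph,
    anchors: AnchorSet,
    k: int = 4,
    K: int = 9,
    eta: float | None = None,
    drop_first: bool = False,
    restarts: int = 50,
    seed: int = 0,
    tau: float = 1e-6,
    keep_frac: float = 0.05,
    reference: LevelTable | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full method on an in-memory graph (library entry point)."""
    timings: dict[str, float] = {}
    anchors.validate(g, K)

    t0 = time.perf_counter()
    eta_used = spectral.default_eta(g) if eta is None else eta
    tm = spectral.transition_matrix(g, eta=eta_used)
    perron = spectral.perron_vector(tm)
    se = spectral.directed_laplacian(tm, perron)
    gaps = spectral.spectral_gaps(se).gaps
    se = spectral.embed(se, k, drop_first=drop_first)
    timings["spectral"] = time.perf_counter() - t0
    logger.info("eigenvalues: %s", np.array2string(se.lambdas, precision=4))
    logger.info("spectral gaps: %s", np.array2string(gaps, precision=4))

    t0 = time.perf_counter()
    dm = hierarchy.pseudo_distance(hierarchy.similarity(se.Z, K))
    timings["distances"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    hr = hierarchy.minimize_levels(
        dm,
        anchors,
        g.labels,
        restarts=restarts,
        seed=seed,
        tau=tau,
        keep_frac=keep_frac,
    )
    timings["minimize"] = time.perf_counter() - t0

    ev = None
    if reference is not None:
        computed = LevelTable(
            entries={lab: float(lv) for lab, lv in zip(g.labels, hr.levels)}
        )
        ev = evaluate(reference, computed)

    cfg = config or RunConfig(
        anchors=dict(anchors.entries),
        k=k,
        K=K,
        eta=eta,
        drop_first=drop_first,
        restarts=restarts,
        seed=seed,
        tau=tau,
        keep_frac=keep_frac,
    )
    return PipelineResult(
        config=cfg,
        graph=g,
        embedding=se,
        gaps=gaps,
        hierarchy=hr,
        evaluation=ev,
        timings=timings,
        eta_used=eta_used,
    )


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute a run described by a config (file-based entry point)."""
    cfg.validate()
    g = graph_io.load_graph(cfg.graph, format=cfg.graph_format)
    entries = dict(cfg.anchors)
    if cfg.anchors_file is not None:
        entries.update(graph_io.load_anchors(cfg.anchors_file).entries)
    anchors = AnchorSet(entries=entries)
    reference = (
        graph_io.load_levels(cfg.reference) if cfg.reference is not None else None
    )
    return run_pipeline_on_graph(
        g,
        anchors,
        k=cfg.k,
        K=cfg.K,
        eta=cfg.eta,
        drop_first=cfg.drop_first,
        restarts=cfg.restarts,
        seed=cfg.seed,
        tau=cfg.tau,
        keep_frac=cfg.keep_frac,
        reference=reference,
        config=cfg,
    )
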