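"""Plain-text I/O for directed graphs, anchor sets, and level tables.

The matrix dialect is a delimited table whose first row and first column
hold node labels; entry (i, j) is the weight of the directed edge from
row-label i (source) to column-label j (target).  The edge-list dialect
is two or three delimited columns: source, target, optional weight.
Anchor and level files are two-column tables mapping a node label to a
level.  Comma and tab delimiters are both accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hierord.errors import (
    DuplicateLabelError,
    GraphFormatError,
    NegativeWeightError,
    NonSquareMatrixError,
    UnknownLabelError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedGraph",
    "AnchorSet",
    "LevelTable",
    "load_graph",
    "load_mat_graph",
    "write_graph",
    "load_anchors",
    "load_levels",
    "write_levels",
    "induced_subgraph",
    "connection_counts",
]


@dataclass(frozen=True)
class DirectedGraph:
    """A labeled directed graph with a nonnegative weight matrix.

    ``W[i, j] > 0`` means information flows from node ``labels[i]`` to
    node ``labels[j]``.  Weights are 0/1 for tract-tracing connectivity
    matrices but any nonnegative weight is accepted (the downstream
    random walk row-normalizes).
    """

    labels: tuple[str, ...]
    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise DuplicateLabelError(f"duplicate node labels: {dupes}")
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise NonSquareMatrixError(f"adjacency matrix has shape {W.shape}")
        if W.shape[0] != len(self.labels):
            raise NonSquareMatrixError(
                f"{len(self.labels)} labels but matrix of order {W.shape[0]}"
            )
        if W.shape[0] < 2:
            raise GraphFormatError("graph needs at least 2 nodes")
        if not np.all(np.isfinite(W)):
            raise GraphFormatError("adjacency matrix contains non-finite entries")
        if np.any(W < 0):
            raise NegativeWeightError("adjacency matrix contains negative weights")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise UnknownLabelError(f"unknown node label {label!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.W, other.W)

    def __hash__(self) -> int:  # frozen dataclass requires a hash
        return hash((self.labels, self.W.tobytes()))


@dataclass(frozen=True)
class AnchorSet:
    """Node labels whose hierarchy levels are fixed before optimization."""

    entries: dict[str, float] = field(default_factory=dict)

    def validate(self, g: DirectedGraph, K: int) -> None:
        if not self.entries:
            from hierord.errors import AnchorError

            raise AnchorError("anchor set is empty; at least one anchor is required")
        for label, level in self.entries.items():
            if label not in g.labels:
                raise UnknownLabelError(f"anchored label {label!r} not in graph")
            if not 0.0 <= float(level) <= float(K):
                from hierord.errors import AnchorError

                raise AnchorError(
                    f"anchor {label!r}={level} outside the level interval [0, {K}]"
                )


@dataclass(frozen=True)
class LevelTable:
    """Mapping node label -> hierarchy level (real or integer)."""

    entries: dict[str, float] = field(default_factory=dict)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def as_array(self, labels: tuple[str, ...] | list[str]) -> np.ndarray:
        return np.array([self.entries[x] for x in labels], dtype=float)


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()
    for line in head:
        if line.strip():
            return "\t" if "\t" in line else ","
    return "\t"


def load_graph(path: str | Path, format: str = "matrix") -> DirectedGraph:
    """Read a directed graph from a delimited-text file.

    ``format="matrix"``: square table with a label header row and label
    first column; row label is the edge source.  ``format="edgelist"``:
    2-3 columns (source, target[, weight]); nodes are created in order of
    first appearance and missing weights default to 1.
    """
    path = Path(path)
    if format == "matrix":
        return _load_matrix(path)
    if format == "edgelist":
        return _load_edgelist(path)
    raise ValueError(f"unknown graph format {format!r}; use 'matrix' or 'edgelist'")


def _load_matrix(path: Path) -> DirectedGraph:
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GraphFormatError(f"cannot parse matrix file {path}: {exc}") from exc
    row_labels = [str(x).strip() for x in df.index]
    col_labels = [str(x).strip() for x in df.columns]
    if len(set(row_labels)) != len(row_labels):
        raise DuplicateLabelError(f"duplicate row labels in {path}")
    if df.shape[0] != df.shape[1]:
        raise NonSquareMatrixError(
            f"matrix file {path} has {df.shape[0]} rows and {df.shape[1]} columns"
        )
    if row_labels != col_labels:
        if set(row_labels) != set(col_labels):
            raise NonSquareMatrixError(
                f"row and column label sets differ in {path}"
            )
        df = df[row_labels]  # reorder columns to the row order
    try:
        W = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise GraphFormatError(f"non-numeric entry in matrix file {path}: {exc}") from exc
    _warn_if_nonbinary(W, path)
    return DirectedGraph(labels=tuple(row_labels), W=W)


def _load_edgelist(path: Path) -> DirectedGraph:
    sep = _sniff_delimiter(path)
    labels: list[str] = []
    index: dict[str, int] = {}
    edges: list[tuple[int, int, float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.split(sep) if p.strip()] if sep in line else line.split()
        if len(parts) not in (2, 3):
            raise GraphFormatError(
                f"{path}:{lineno}: expected 2-3 columns, got {len(parts)}: {raw!r}"
            )
        src, dst = parts[0].strip(), parts[1].strip()
        if len(parts) == 3:
            try:
                w = float(parts[2])
            except ValueError:
                raise GraphFormatError(
                    f"{path}:{lineno}: unparseable weight {parts[2]!r}"
                ) from None
        else:
            w = 1.0
        if w < 0:
            raise NegativeWeightError(f"{path}:{lineno}: negative weight {w}")
        for lab in (src, dst):
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
        edges.append((index[src], index[dst], w))
    n = len(labels)
    if n < 2:
        raise GraphFormatError(f"edge list {path} defines fewer than 2 nodes")
    W = np.zeros((n, n))
    for i, j, w in edges:
        W[i, j] = w
    _warn_if_nonbinary(W, path)
    return DirectedGraph(labels=tuple(labels), W=W)


def _warn_if_nonbinary(W: np.ndarray, path: Path) -> None:
    if not np.all(np.isin(W[np.isfinite(W)], (0.0, 1.0))):
        logger.warning(
            "graph %s has non-binary weights; they are passed through unchanged "
            "(the transition matrix normalizes rows)",
            path,
        )


def load_mat_graph(path: str | Path, key: str | None = None) -> DirectedGraph:
    """Convenience reader for MATLAB container files holding an adjacency matrix.

    Looks for a square 2-D numeric array (variable ``key`` if given, else
    the first square array found) and an optional cell array of labels.
    Provided for working with published connectivity matrices distributed
    as ``.mat``; all core I/O and tests use plain text.
    """
    from scipy.io import loadmat

    data = loadmat(str(path))
    arrays = {
        k: np.asarray(v)
        for k, v in data.items()
        if not k.startswith("__") and isinstance(v, np.ndarray)
    }
    W = None
    if key is not None:
        W = np.asarray(arrays[key], dtype=float)
    else:
        for v in arrays.values():
            if v.ndim == 2 and v.shape[0] == v.shape[1] and v.shape[0] >= 2:
                if np.issubdtype(v.dtype, np.number):
                    W = v.astype(float)
                    break
    if W is None:
        raise GraphFormatError(f"no square numeric matrix found in {path}")
    labels: tuple[str, ...] | None = None
    for v in arrays.values():
        if v.dtype == object and v.size == W.shape[0]:
            labels = tuple(str(np.squeeze(x)) for x in v.ravel())
            break
    if labels is None:
        labels = tuple(f"N{i}" for i in range(W.shape[0]))
    return DirectedGraph(labels=labels, W=W)


def write_graph(g: DirectedGraph, path: str | Path, sep: str = "\t") -> None:
    """Write a graph in the matrix dialect (label header row and column)."""
    df = pd.DataFrame(g.W, index=list(g.labels), columns=list(g.labels))
    df.to_csv(Path(path), sep=sep)


def induced_subgraph(g: DirectedGraph, keep: list[str] | tuple[str, ...]) -> DirectedGraph:
    """Principal submatrix on the labels in ``keep``, preserving keep's order."""
    idx = [g.index(lab) for lab in keep]
    if len(set(keep)) != len(keep):
        raise DuplicateLabelError(f"duplicate labels in keep list: {list(keep)}")
    W = g.W[np.ix_(idx, idx)]
    return DirectedGraph(labels=tuple(keep), W=W)


def connection_counts(g: DirectedGraph) -> dict[str, int]:
    """Count directed edges and connected (unordered) node pairs.

    Published connectivity datasets quote "connections" under either
    convention, so both are reported: ``directed_edges`` counts nonzero
    off-diagonal entries of W; ``connected_pairs`` counts unordered pairs
    linked in at least one direction.
    """
    A = g.W > 0
    np.fill_diagonal(A, False)
    directed = int(A.sum())
    pairs = int(np.triu(A | A.T, k=1).sum())
    return {"directed_edges": directed, "connected_pairs": pairs}


def _load_two_column(path: Path) -> dict[str, float]:
    sep = _sniff_delimiter(path)
    entries: dict[str, float] = {}
    lines = path.read_text().splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in (line.split(sep) if sep in line else line.split())]
        if len(parts) != 2:
            raise GraphFormatError(
                f"{path}:{lineno}: expected 2 columns, got {len(parts)}: {raw!r}"
            )
        label, value = parts
        if lineno == 1:
            try:
                float(value)
            except ValueError:
                continue  # header row
        try:
            level = float(value)
        except ValueError:
            raise GraphFormatError(
                f"{path}:{lineno}: unparseable level {value!r}"
            ) from None
        if label in entries:
            raise DuplicateLabelError(f"{path}:{lineno}: duplicate label {label!r}")
        entries[label] = level
    return entries


def load_anchors(path: str | Path) -> AnchorSet:
    """Read a two-column label -> fixed-level anchor table."""
    return AnchorSet(entries=_load_two_column(Path(path)))


def load_levels(path: str | Path) -> LevelTable:
    """Read a two-column label -> level table (e.g. a reference hierarchy)."""
    return LevelTable(entries=_load_two_column(Path(path)))


def write_levels(t: LevelTable, path: str | Path, sep: str = "\t") -> None:
    """Write a level table as two-column delimited text with a header row.

    Row order follows the table's own (insertion) order so that a
    read-back reproduces the table exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"node{sep}level\n")
        for label, level in t.entries.items():
            fh.write(f"{label}{sep}{level!r}\n")
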