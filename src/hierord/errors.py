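"""Exception hierarchy for hierord.

Each loader/validator failure mode raises its own class so callers (and
the CLI) can report the offending construct precisely.
"""


class HierordError(Exception):
    """Base class for all hierord errors."""


class GraphFormatError(HierordError):
    """A graph file could not be parsed in the declared dialect."""


class NonSquareMatrixError(GraphFormatError):
    """Adjacency matrix dialect requires equal row and column label sets."""


class DuplicateLabelError(GraphFormatError):
    """Node labels must be unique."""


class NegativeWeightError(GraphFormatError):
    """Edge weights must be nonnegative."""


class UnknownLabelError(HierordError):
    """A referenced node label does not exist in the graph."""


class AnchorError(HierordError):
    """Anchor set is empty, out of range, or references unknown nodes."""


class ConnectivityError(HierordError):
    """A generated graph failed the weak-connectivity requirement."""


class SpectralError(HierordError):
    """Eigen-decomposition failed or produced a degenerate result."""


class OptimizationError(HierordError):
    """All restarts of the level optimizer failed."""


class ConfigError(HierordError):
    """A pipeline configuration field is missing or invalid."""
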