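"""Exception hierarchy for cageconform.

Exit-code mapping used by the CLI: ConfigError -> 2, everything else
derived from CageError -> 3.
"""


class CageError(Exception):
    """Base class for all cageconform errors."""


class ParseError(CageError):
    """A structure or table file could not be parsed."""


class FrameError(ParseError):
    """Inconsistent frames in a multi-frame trajectory."""


class TopologyError(CageError):
    """The structure does not match the expected lantern-cage topology."""


class AmbiguityError(TopologyError):
    """Topology perception found no unique answer (e.g. central ring)."""


class GraphError(CageError):
    """A molecular-graph precondition (e.g. connectivity) is violated."""


class GeometryError(CageError):
    """Degenerate or infeasible geometry."""


class DataError(CageError):
    """Tabular input violates its contract (lengths, duplicates, ranges)."""


class ConfigError(CageError):
    """Invalid configuration (thresholds, temperature, spec parameters)."""
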