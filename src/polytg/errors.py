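"""Exception hierarchy for polytg."""


class PolytgError(Exception):
    """Base class for all polytg errors."""


class ParseError(PolytgError, ValueError):
    """SMILES string could not be parsed."""


class StructureError(PolytgError, ValueError):
    """Parsed molecule violates the repeat-unit conventions
    (wrong number of attachment points, disconnected heavy-atom graph, ...)."""


class UnsupportedElementError(PolytgError, ValueError):
    """Element outside the supported set {C, N, O, S, F, Cl, Br, Si, P}."""


class ComputationError(PolytgError, ValueError):
    """A descriptor could not be evaluated (e.g. empty backbone, delta <= 0)."""


class DataError(PolytgError, ValueError):
    """Tabular input violates a precondition (too few rows, k > n, ...)."""


class SchemaError(PolytgError, ValueError):
    """Input table is missing required columns or has malformed rows."""


class ConfigError(PolytgError, ValueError):
    """Invalid configuration value (e.g. test fraction outside (0, 1))."""


class FitError(PolytgError, RuntimeError):
    """Model fitting failed (e.g. disconnected neighbour graph)."""
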