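"""Exception hierarchy for dendristab."""


class DendristabError(Exception):
    """Base class for all package-specific errors."""


class StructureError(DendristabError):
    """A trajectory violates a structural invariant (e.g. atom-count change)."""


class TrajectoryParseError(DendristabError):
    """A coordinate file could not be parsed; carries a location."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class TopologyValidationError(DendristabError):
    """A topology sidecar is inconsistent with itself or its trajectory."""


class KineticsDataError(DendristabError):
    """A kinetics table violates its contract (ordering, row count, units)."""


class PlacementError(DendristabError):
    """Synthetic placement failed (density too high for hard-core rejection)."""
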