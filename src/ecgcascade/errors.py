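"""Exception hierarchy shared by all pipeline stages."""


class EcgCascadeError(Exception):
    """Base class for all package errors."""


class ParameterError(EcgCascadeError, ValueError):
    """A configuration or argument value violates its contract."""


class FormatError(EcgCascadeError, ValueError):
    """An on-disk file is not in a recognized/parseable format."""


class ChannelError(EcgCascadeError, ValueError):
    """The requested signal channel is absent from a record."""


class ShapeError(EcgCascadeError, ValueError):
    """Array/sequence dimensions are inconsistent with the contract."""


class CapacityError(EcgCascadeError, ValueError):
    """A request exceeds what the data can supply (beats, normals, ...)."""


class DegenerateInputError(EcgCascadeError, ValueError):
    """Input is degenerate for the operation (e.g. constant signal)."""


class RateError(EcgCascadeError, ValueError):
    """A record's sampling rate does not match the required target rate."""


class LeakageError(EcgCascadeError, RuntimeError):
    """Subject overlap between data partitions that must be disjoint."""


class CoverageError(EcgCascadeError, ValueError):
    """A split assignment does not cover every subject present."""


class InfeasibleError(EcgCascadeError, ValueError):
    """Fewer subjects than splits: no valid assignment exists."""
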