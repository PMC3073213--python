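"""Exception hierarchy for the eoseg pipeline."""


class EosegError(Exception):
    """Base class for all eoseg errors."""


class FormatError(EosegError):
    """A file on disk does not match the expected layout (pages, sidecar, shapes)."""


class DimensionError(EosegError):
    """Array shapes or band counts of two operands do not agree."""


class ParameterError(EosegError):
    """A parameter is outside its valid range."""


class DataError(EosegError):
    """Input data are unusable (empty class, non-finite values, too few samples)."""


class SelectionError(EosegError):
    """Band-pair selection is inapplicable to the given mean-error vector."""


class GenerationError(EosegError):
    """The phantom generator could not realize the requested scene."""
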