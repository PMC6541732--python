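"""Exception hierarchy shared across the package."""


class CliffCensusError(Exception):
    """Base class for all package errors."""


class FormatError(CliffCensusError):
    """A tabular input file is missing required columns or is malformed."""


class ValidationError(CliffCensusError):
    """Input data violates a domain invariant (e.g. a negative count)."""


class LookupError_(CliffCensusError):
    """A referenced identifier (cell id, area id) does not exist."""


class InsufficientDataError(CliffCensusError):
    """Too few observations for the requested computation."""
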