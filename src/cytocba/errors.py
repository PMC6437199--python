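"""Exception hierarchy for the cytometric cell-based assay pipeline.

Every error raised by the package derives from :class:`CytocbaError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors with a single ``except`` clause.
"""


class CytocbaError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CytocbaError):
    """A file does not conform to the expected on-disk format."""


class ChannelMappingError(FormatError):
    """An instrument channel name could not be mapped to a canonical channel."""


class ValidationError(CytocbaError):
    """In-memory data violates a structural invariant."""


class ParameterError(CytocbaError):
    """A simulation or gating parameter is outside its admissible range."""


class DomainError(CytocbaError):
    """A numeric argument is outside the domain of an operation."""


class PairingError(ValidationError):
    """A test sample lacks its paired cell line in the manifest."""


class CalibrationPrerequisiteError(ValidationError):
    """A required background/control sample is missing."""


class CalibrationError(CytocbaError):
    """A threshold could not be calibrated from the provided control."""


class InsufficientEventsError(CytocbaError):
    """Too few events for a robust gate fit."""


class DegenerateGeometryError(CytocbaError):
    """Scatter geometry is singular (e.g. all events at one coordinate)."""


class InsufficientPopulationError(CytocbaError):
    """The gated population is too small for a stable PE fraction."""


class SchemaError(CytocbaError):
    """A tabular input is missing required columns."""


class ParseError(CytocbaError):
    """A tabular input contains an unparseable value."""
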