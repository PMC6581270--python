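"""Exception hierarchy for the NTA toolkit.

Every domain failure raises a subclass of :class:`NTAError`, so callers
(and the CLI) can distinguish bad input data from programming errors.
"""


class NTAError(Exception):
    """Base class for all toolkit errors."""


class VersionError(NTAError):
    """The file preamble has no parseable software-version line."""


class FormatError(NTAError):
    """The file or table violates the experiment-summary dialect."""


class GridMismatchError(NTAError):
    """Size-bin grids disagree where they must be identical."""


class SchemaError(NTAError):
    """A measurement name does not fit the declared sample-name schema."""


class DilutionError(NTAError):
    """The dilution token is not a positive number."""


class SampleSizeError(NTAError):
    """Too few observations for the requested test."""


class DegenerateError(NTAError):
    """Input has zero variance where spread is required."""


class GroupCountError(NTAError):
    """Wrong number of groups for the requested comparison."""


class EmptyInputError(NTAError):
    """An operation that needs data received an empty table."""
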