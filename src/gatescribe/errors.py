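"""Exception hierarchy shared across the package."""


class GatescribeError(Exception):
    """Base class for all package errors."""


class FormatError(GatescribeError):
    """Malformed on-disk input (CSV/FCS/marker table)."""


class ParseError(FormatError):
    """Non-numeric or syntactically invalid payload, with location info."""


class UnsupportedFormatError(FormatError):
    """File is recognizable but uses an unsupported variant."""


class CorruptFileError(FormatError):
    """Internal offsets or sizes are inconsistent with the file."""


class ParameterError(GatescribeError):
    """Out-of-range or inconsistent user parameter."""


class SpecificationError(GatescribeError):
    """Contradictory or unsatisfiable marker-table specification."""


class DegenerateDataError(GatescribeError):
    """Data cannot support the requested model (e.g. constant input)."""
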