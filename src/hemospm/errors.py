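"""Exception hierarchy shared across the package."""


class HemoSPMError(Exception):
    """Base class for all package errors."""


class FormatError(HemoSPMError):
    """A table or config file does not have the expected structure."""


class DataError(HemoSPMError):
    """Structurally valid input carries inconsistent or unusable data."""


class ContractError(HemoSPMError):
    """An operation was called with arguments violating its preconditions."""


class InsufficientDataError(DataError):
    """Too few observations to perform the requested operation."""
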