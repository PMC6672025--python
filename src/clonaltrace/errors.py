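"""Exception types shared across the package."""


class ClonalTraceError(Exception):
    """Base class for package errors."""


class ConfigurationError(ClonalTraceError):
    """A manifest, config file, or label set is inconsistent."""


class ParseError(ClonalTraceError):
    """An input record could not be interpreted; the message names the record."""


class ContractViolation(ClonalTraceError):
    """An internal pre-condition was violated (e.g. unassigned mutation)."""
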