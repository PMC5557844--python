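"""Exception hierarchy shared across the package."""


class StressDielError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StressDielError, ValueError):
    """Invalid simulation or run configuration."""


class FormatError(StressDielError, ValueError):
    """Malformed input file (ragged rows, duplicate ids, unknown codes)."""


class ValidationError(StressDielError, ValueError):
    """Data violates a stated invariant (e.g. nonpositive linear intensity)."""


class PairingError(StressDielError, ValueError):
    """A stressed sample (or a Ct record) lacks its matched control."""
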