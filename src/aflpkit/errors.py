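"""Exception types shared across the package."""


class AflpkitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AflpkitError):
    """A file does not conform to the expected external format."""


class ValidationError(AflpkitError):
    """Data violates a container invariant or an operation precondition."""
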