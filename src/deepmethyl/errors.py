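"""Exception types shared across the package."""


class DeepMethylError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DeepMethylError):
    """A file could not be parsed in the named format (names the line/record)."""


class ValidationError(DeepMethylError):
    """Parsed data violates a domain invariant (lists offending ids where possible)."""


class StageError(DeepMethylError):
    """A pipeline stage cannot run, e.g. a missing upstream artifact."""
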