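"""Exception types shared across the package."""


class M6ASigError(Exception):
    """Base class for all package errors."""


class ValidationError(M6ASigError):
    """An in-memory object violates a data-model invariant."""


class ParseError(M6ASigError):
    """An on-disk artifact could not be parsed."""
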