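"""Exception hierarchy shared across the package."""


class GenemetaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GenemetaError):
    """An input table is structurally invalid (e.g. a required column is missing)."""


class ValidationError(GenemetaError):
    """A value violates a contract (negative count, duplicate id, mixed models...)."""


class DomainError(GenemetaError):
    """An operation was called on input outside its mathematical domain."""


class DegenerateInputError(DomainError):
    """Input is formally valid but statistically degenerate (e.g. monomorphic sample)."""
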