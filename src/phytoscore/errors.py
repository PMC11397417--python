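"""Exception hierarchy shared by all pipeline stages."""


class PhytoscoreError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PhytoscoreError):
    """Input file or config does not match the expected schema."""


class ParseError(PhytoscoreError):
    """A cell or field could not be parsed."""


class ValidationError(PhytoscoreError):
    """A table or config violates an invariant."""


class DomainError(PhytoscoreError):
    """An argument is outside the mathematical domain of an operation."""


class DesignError(PhytoscoreError):
    """The experimental design is insufficient for the requested analysis."""


class AlignmentError(PhytoscoreError):
    """Variable ordering between two objects does not match."""
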