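"""Exception hierarchy for panel evaluation."""


class PanevalError(Exception):
    """Base class for all package errors."""


class ValidationError(PanevalError):
    """Malformed input: ragged tables, duplicate labels, missing cells, bad config."""


class DomainError(PanevalError):
    """Numerically inadmissible input: non-positive reciprocal, degenerate weights, ..."""


class DegenerateColumnError(DomainError):
    """A column carries no information (constant / all-zero)."""
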