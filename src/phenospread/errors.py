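"""Exception hierarchy.

All phenospread-specific errors derive from :class:`PhenospreadError` so
callers can catch the package's failures with a single except clause.
Lookup failures (unknown CUI, unknown patient) raise plain ``KeyError``.
"""


class PhenospreadError(Exception):
    """Base class for all phenospread errors."""


class ParseError(PhenospreadError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PhenospreadError, ValueError):
    """A parsed value violates a domain invariant (range, enum, uniqueness)."""


class ParameterError(PhenospreadError, ValueError):
    """A function argument violates its precondition."""
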