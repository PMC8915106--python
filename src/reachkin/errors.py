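"""Exception hierarchy.

All failures raised by this package derive from :class:`ReachkinError`,
so callers can catch one type at pipeline level. ``ValidationError`` and
``ParameterError`` additionally derive from :class:`ValueError` so that
generic numeric code treats them idiomatically.
"""


class ReachkinError(Exception):
    """Base class for all package errors."""


class FormatError(ReachkinError):
    """An input file does not have the expected layout (e.g. missing column)."""


class ValidationError(ReachkinError, ValueError):
    """Input data violates a structural invariant (length, monotonicity, ...)."""


class ParameterError(ReachkinError, ValueError):
    """A configuration value is outside its admissible range."""
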