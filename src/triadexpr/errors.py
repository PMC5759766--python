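"""Exception hierarchy.

All user-facing failures derive from :class:`TriadExprError` so the CLI can
map them to a user-error exit code; anything else is an internal error.
"""


class TriadExprError(Exception):
    """Base class for all errors raised by triadexpr."""


class ParameterError(TriadExprError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class DesignError(TriadExprError, ValueError):
    """The sample design is inconsistent with the requested operation."""


class ParseError(TriadExprError, ValueError):
    """A malformed input file; the message locates the offending cell/line."""


class NormalizationError(TriadExprError):
    """Size factors cannot be estimated from the given count matrix."""


class InputError(TriadExprError, ValueError):
    """Inconsistent in-memory inputs (e.g. mismatched gene universes)."""


class DegenerateDataError(TriadExprError):
    """Data degenerate for the requested statistic (e.g. zero variance)."""
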