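"""Exception hierarchy for stabkin.

All stabkin-raised errors derive from :class:`StabkinError` so callers can
catch the package's failures with a single except clause; the leaf classes
distinguish bad input values, degenerate fits, under-powered designs, and
file/config problems.
"""


class StabkinError(Exception):
    """Base class for all stabkin errors."""


class InvalidInputError(StabkinError, ValueError):
    """An input value violates a precondition (negative time, zero reference area, ...)."""


class SingularFitError(StabkinError):
    """A regression cannot be computed (zero predictor variance, zero slope inversion)."""


class InsufficientDesignError(StabkinError):
    """Too few points or levels to support the requested fit."""


class InsufficientReplicatesError(StabkinError):
    """A replicate group is too small for dispersion statistics."""


class SchemaError(StabkinError):
    """A CSV file does not match the documented column schema."""


class DataParseError(StabkinError):
    """A CSV cell could not be parsed as a number."""


class ConfigError(StabkinError):
    """A run configuration is malformed; the message names the offending keys."""
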