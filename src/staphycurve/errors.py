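"""Exception hierarchy for staphycurve.

All package errors derive from :class:`StaphyCurveError` so callers can
catch everything with one clause; the subclasses distinguish bad files,
bad values, bad geometry spans, and bad call sequences.
"""


class StaphyCurveError(Exception):
    """Base class for all staphycurve errors."""


class ValidationError(StaphyCurveError, ValueError):
    """An object violates one of its documented invariants."""


class ParseError(StaphyCurveError, ValueError):
    """A profile or cohort file could not be parsed."""


class SpanError(StaphyCurveError, ValueError):
    """A profile does not cover the lateral span an operation requires."""


class DomainError(StaphyCurveError, ValueError):
    """A numeric input lies outside the mathematical domain of a formula."""


class StateError(StaphyCurveError, RuntimeError):
    """An operation was called in the wrong object state (e.g. re-scaling)."""


class ConfigError(StaphyCurveError, ValueError):
    """A generator or pipeline configuration is inconsistent."""
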