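"""Exception hierarchy.

Analyses distinguish three failure modes: malformed input (schema /
validation), invalid parameters, and well-formed data on which a metric is
simply not defined (too few trials, zero variance, ...).  The last group is
signalled explicitly rather than returning NaN silently, because inclusion
decisions materially shape longitudinal results and must be loggable.
"""


class PopdisorgError(Exception):
    """Base class for all package errors."""


class SchemaError(PopdisorgError):
    """A session bundle is structurally malformed (missing fields, bad version)."""


class ValidationError(PopdisorgError):
    """A session violates a domain invariant (non-monotone times, empty trials...)."""


class ParameterError(PopdisorgError, ValueError):
    """An analysis or generator parameter is out of its valid range."""


class UndefinedMetricError(PopdisorgError):
    """The requested metric is undefined on this input (e.g. zero denominator)."""


class SessionExcludedError(PopdisorgError):
    """The session fails an inclusion filter (e.g. < 20 completed trials)."""


class MatchingFailedError(PopdisorgError):
    """Firing-rate matching cannot reach the target band on this population."""
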