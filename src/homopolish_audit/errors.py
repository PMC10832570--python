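"""Exception hierarchy for the audit pipeline.

All exceptions derive from :class:`AuditError` so callers can catch pipeline
failures with a single ``except`` clause while still distinguishing bad user
configuration from malformed input data and internal bookkeeping problems.
"""


class AuditError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(AuditError):
    """A parameter or configuration value is invalid; names the offending field."""


class InputDataError(AuditError):
    """Input data (sequence, alignment, table) violates a documented contract."""


class ConsistencyError(AuditError):
    """Internal cross-stage bookkeeping does not line up (e.g. call without census cell)."""
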