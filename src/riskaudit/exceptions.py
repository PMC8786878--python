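"""Exception hierarchy for riskaudit.

All library errors derive from :class:`RiskAuditError` so callers can catch
everything the package raises with a single ``except`` clause.
"""


class RiskAuditError(Exception):
    """Base class for all riskaudit errors."""


class ConfigurationError(RiskAuditError):
    """A configuration object violates one of its invariants."""


class SchemaError(RiskAuditError):
    """Tabular input does not match the expected schema (column, level, or row)."""


class UndefinedMetricError(RiskAuditError):
    """A metric is undefined on the given input (e.g. single-class labels)."""


class UndefinedIntervalError(RiskAuditError):
    """A confidence interval cannot be formed (e.g. zero trials)."""


class UnsupportedInputError(RiskAuditError):
    """The operation needs information the input object does not carry."""


class FitError(RiskAuditError):
    """Model fitting failed (e.g. single-class training labels)."""
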