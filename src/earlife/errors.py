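"""Exception hierarchy shared across the pipeline.

Errors are split by provenance so that callers (and the CLI exit codes)
can distinguish a bad configuration from bad data from a sampler that
did not converge.
"""


class EarlifeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EarlifeError):
    """Invalid protocol, model, or pipeline configuration."""


class SchemaError(EarlifeError):
    """Input table is missing a column required by an operation."""


class ValidationError(EarlifeError):
    """Input values violate an invariant (e.g. k > n)."""


class AggregationError(EarlifeError):
    """Count rows cannot be combined (e.g. mismatched denominators)."""


class DataError(EarlifeError):
    """Data are degenerate for the requested computation."""


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics exceeded their thresholds; results are flagged."""
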