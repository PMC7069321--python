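"""Typed exceptions for the reinfiso pipeline.

Every malformed input maps to one of these; callers never see a
half-loaded dataset or a silent NaN.
"""


class ReinfisoError(Exception):
    """Base class for all package errors."""


class SchemaError(ReinfisoError):
    """A file or record is structurally wrong: missing column, unknown
    enum token, term referencing an unknown factor."""


class ValidationError(ReinfisoError):
    """A record violates a domain invariant (negative time, association
    times exceeding trial duration, negative count)."""


class ConsistencyError(ReinfisoError):
    """Cross-record invariant violated: a population mapped to two
    geographic contexts, or a duplicate behavior-count key."""


class DomainError(ReinfisoError):
    """An operation was called with arguments outside its domain
    (mismatched list lengths, empty behavior subset, negative input)."""


class ConfigError(ReinfisoError):
    """A simulation or pipeline configuration is invalid; raised before
    any sampling or I/O happens."""


class FitError(ReinfisoError):
    """A model could not be fitted: rank-deficient design, a variance
    group too small, or non-convergence."""
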