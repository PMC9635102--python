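"""Exception hierarchy for the triage pipeline.

All domain errors derive from :class:`TriageError` so callers (and the CLI)
can catch one base class and translate to a non-zero exit code.
"""


class TriageError(Exception):
    """Base class for all domain errors raised by this package."""


class SchemaError(TriageError):
    """Input table header/keys do not match the registry schema."""


class DuplicateIdError(TriageError):
    """A candidate_id occurs more than once within one registry."""


class ValueTokenError(TriageError):
    """A cell holds a token outside the permitted vocabulary for its field."""


class ReferentialError(TriageError):
    """An assessment references a candidate absent from the registry."""


class UnresolvedConflictError(TriageError):
    """Reviewers disagree on a criterion and no adjudicator level exists."""


class CoverageError(TriageError):
    """A match profile does not cover the configured criterion set."""


class NotRankableError(TriageError):
    """Ranking requested for a development phase that is described, not ranked."""


class MissingAssessmentError(TriageError):
    """A retained clinical candidate-indication pair lacks reviewer records."""


class ScopeError(TriageError):
    """An operation restricted to one registry stratum received other rows."""


class EmptyInputError(TriageError):
    """A summary was requested over an empty registry."""


class ConfigError(TriageError):
    """A scoring-scheme or generator configuration failed validation."""


class InfeasibleConfigError(ConfigError):
    """A planted rank band is unreachable on the discrete score lattice."""


class JoinError(TriageError):
    """A match profile has no corresponding ranked entry (or vice versa)."""
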