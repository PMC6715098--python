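"""Exception hierarchy shared across the package."""


class CogtrainError(Exception):
    """Base class for all package-specific errors."""


class CatalogError(CogtrainError):
    """Invalid or inconsistent exercise catalog input."""


class NormsLookupError(CogtrainError, LookupError):
    """An assessment or exercise is missing from a normative reference."""


class IncompleteIntakeError(CogtrainError):
    """Baseline test scores do not cover every cognitive domain."""


class RefreshError(CogtrainError):
    """A profile refresh was requested without usable training records."""


class SchedulingError(CogtrainError):
    """A session plan cannot be filled under the current constraints."""


class UnknownExerciseError(CogtrainError, LookupError):
    """An exercise id is absent from the cohort score distributions."""


class DegenerateDistributionError(CogtrainError):
    """A cohort score distribution has zero spread and cannot standardize."""


class InsufficientCohortError(CogtrainError):
    """The comparison cohort is too small to compute a target zone."""


class MalformedRecordError(CogtrainError):
    """A session record is internally inconsistent (e.g. ends before it starts)."""


class InvalidTransitionError(CogtrainError):
    """A ticket action is not valid in the ticket's current status."""


class InvalidFlagError(CogtrainError):
    """A flag was used in a role its severity does not permit."""


class SquadFullError(CogtrainError):
    """A CheerSquad already holds the maximum number of members."""


class StateError(CogtrainError):
    """Engine state was used out of order (e.g. completing sessions out of sequence)."""


class StateLoadError(CogtrainError):
    """A persisted state file could not be parsed."""


class StateVersionError(StateLoadError):
    """A persisted state file has an unsupported schema version."""
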