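"""The full training stack wired together for one participant at a time.

:class:`TrainingEngine` binds a catalog, a normative reference and cohort
score distributions to the profile, scheduling, scoring and adherence
rules.  It drives the participant lifecycle: intake builds the baseline
profile; session results update attempt histories, raise flags/tickets/
emails, notify the CheerSquad and, at the range boundaries, refresh the
profile that shapes subsequent sandwiches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Mapping

from .adherence import (
    AdherenceTracker,
    CheerSquad,
    Flag,
    MilestoneNotification,
    evaluate_exercise_flags,
    evaluate_session_flags,
    milestone_events,
)
from .catalog import ExerciseCatalog
from .config import EngineConfig
from .errors import SchedulingError, StateError
from .profiles import (
    REFRESH_POINTS,
    CognitiveProfile,
    NormativeReference,
    build_baseline_profile,
    refresh_profile,
)
from .scheduler import (
    ModuleState,
    NextSession,
    SessionPlan,
    make_session_plan,
    next_session as _next_session,
    profile_epoch_for_session,
    session_rng,
)
from .scoring import ExerciseCohortStats, ExerciseResult, SessionRecord

__all__ = ["ParticipantState", "SessionOutcome", "TrainingEngine"]


@dataclass
class ParticipantState:
    """Everything the engine tracks for one participant."""

    participant_id: str
    profiles: dict[str, CognitiveProfile]
    module: ModuleState
    tracker: AdherenceTracker
    records: list[SessionRecord] = field(default_factory=list)
    attempt_counts: dict[str, int] = field(default_factory=dict)
    last_attempt: dict[str, ExerciseResult] = field(default_factory=dict)
    squad: CheerSquad | None = None
    notifications: list[MilestoneNotification] = field(default_factory=list)

    @property
    def baseline_profile(self) -> CognitiveProfile:
        return self.profiles["baseline"]

    def current_profile(self) -> CognitiveProfile:
        idx = self.module.next_index or 30
        epoch = profile_epoch_for_session(idx)
        if epoch not in self.profiles:
            raise SchedulingError(f"no profile available for epoch {epoch!r}")
        return self.profiles[epoch]

    def attempt_number(self, exercise_id: str) -> int:
        """1-based attempt number the next attempt of this exercise will have."""
        return self.attempt_counts.get(exercise_id, 0) + 1


@dataclass(frozen=True)
class SessionOutcome:
    """Events produced by ingesting one session record."""

    flags: tuple[Flag, ...]
    escalations: tuple[Flag, ...]
    notifications: tuple[MilestoneNotification, ...]
    refreshed_epoch: str | None


class TrainingEngine:
    def __init__(
        self,
        catalog: ExerciseCatalog,
        norms: NormativeReference,
        cohort_stats: ExerciseCohortStats,
        config: EngineConfig | None = None,
        refresh_stats: Mapping[int, ExerciseCohortStats] | None = None,
    ):
        self.catalog = catalog
        self.norms = norms
        self.cohort_stats = cohort_stats
        self.config = config if config is not None else EngineConfig()
        # optional per-refresh-range cohort distributions; the normative
        # cohort's first-attempt distributions are the fallback reference
        self.refresh_stats = dict(refresh_stats or {})

    # -- lifecycle -------------------------------------------------------

    def intake(
        self,
        participant_id: str,
        test_scores: Mapping[str, float],
        start: datetime,
        seed: int | None = None,
    ) -> ParticipantState:
        """Build the baseline profile and open a fresh module."""
        profile = build_baseline_profile(
            test_scores, self.norms, self.catalog, participant_id
        )
        module = ModuleState(
            participant_id=participant_id,
            start=start,
            seed=self.config.seed if seed is None else seed,
        )
        return ParticipantState(
            participant_id=participant_id,
            profiles={"baseline": profile},
            module=module,
            tracker=AdherenceTracker(self.config.adherence),
        )

    def plan_for_session(self, state: ParticipantState, session_index: int) -> SessionPlan:
        epoch = profile_epoch_for_session(session_index)
        if epoch not in state.profiles:
            raise SchedulingError(f"no profile available for epoch {epoch!r}")
        return make_session_plan(
            state.profiles[epoch],
            self.catalog,
            session_index,
            session_rng(state.module.seed, session_index),
        )

    def next_plan(self, state: ParticipantState, now: datetime) -> NextSession:
        """The plan for the lowest uncompleted session, or a blocked status."""
        idx = state.module.next_index
        if idx is None:
            return NextSession(status="completed_all")
        if now > state.module.window_end:
            return NextSession(status="module_ended")
        return NextSession(status="available", plan=self.plan_for_session(state, idx))

    def record_session(
        self, state: ParticipantState, record: SessionRecord
    ) -> SessionOutcome:
        """Ingest one completed session: flags, escalation, emails, refresh."""
        record.validate()
        expected = state.module.next_index
        if record.session_index != expected:
            raise StateError(
                f"sessions complete in order: expected {expected}, "
                f"got {record.session_index}"
            )
        previous_end = state.records[-1].end if state.records else None
        flags: list[Flag] = []
        for result in record.results:
            flags.extend(
                evaluate_exercise_flags(
                    result,
                    state.last_attempt.get(result.exercise_id),
                    self.config.adherence,
                )
            )
        flags.extend(
            evaluate_session_flags(record, previous_end, self.config.adherence)
        )
        flags.sort(key=lambda f: f.timestamp)
        escalations: list[Flag] = []
        for flag in flags:
            escalations.extend(state.tracker.submit(flag))
        for result in record.results:
            state.attempt_counts[result.exercise_id] = (
                state.attempt_counts.get(result.exercise_id, 0) + 1
            )
            state.last_attempt[result.exercise_id] = result
        state.records.append(record)
        state.module.complete_session(record.session_index, record.end)

        notifications: tuple[MilestoneNotification, ...] = ()
        if state.squad is not None and record.session_index in state.squad.milestones:
            new = [
                n
                for n in milestone_events(state.module, state.squad)
                if n.milestone_session == record.session_index
            ]
            state.notifications.extend(new)
            notifications = tuple(new)

        refreshed = self._maybe_refresh(state, record.session_index)
        return SessionOutcome(
            flags=tuple(flags),
            escalations=tuple(escalations),
            notifications=notifications,
            refreshed_epoch=refreshed,
        )

    def _maybe_refresh(self, state: ParticipantState, completed_index: int) -> str | None:
        boundary = completed_index + 1
        if boundary not in REFRESH_POINTS:
            return None
        epoch = f"refresh-{boundary}"
        stats = self.refresh_stats.get(boundary, self.cohort_stats)
        previous = state.profiles[profile_epoch_for_session(completed_index)]
        state.profiles[epoch] = refresh_profile(
            previous, state.records, stats, boundary, self.catalog
        )
        return epoch
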