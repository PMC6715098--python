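"""Flag rules, escalation, tickets, notification throttling and CheerSquad.

Poor *performance* raises red flags: more incorrect than correct responses
in an exercise, zero correct answers, failing to reach an exercise's
predefined minimum score, or scoring at least 10% worse than on the
previous attempt of the same exercise across sessions.  Poor *adherence*
raises orange flags: a session longer than 90 minutes (strict) or an
absence of 72 hours or more between sessions (inclusive).  Every third
orange flag escalates into an adherence red flag.

Red flags open trainer tickets and trigger an automatic participant email;
orange flags only notify trainers until they escalate.  Automatic
participant emails are capped at one per 72 hours — an email is emitted
only when none was emitted in the preceding window, so any sliding window
of that length contains at most one.  Tickets follow a fixed lifecycle:
open -> assigned -> resolved, with handover between trainers while
assigned.

Participants may register a CheerSquad of up to five friends or family
members who are notified whenever the participant crosses a training
milestone (by default completion of sessions 1, 10, 20 and 30).

All "emails" here are events appended to an outbox log; nothing is sent.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Sequence

from .errors import (
    InvalidFlagError,
    InvalidTransitionError,
    MalformedRecordError,
    SquadFullError,
)
from .scheduler import ModuleState
from .scoring import ExerciseResult, SessionRecord

__all__ = [
    "FlagCause",
    "Severity",
    "Flag",
    "AdherenceConfig",
    "DEFAULT_MILESTONES",
    "MAX_SQUAD_SIZE",
    "evaluate_exercise_flags",
    "evaluate_session_flags",
    "escalate",
    "TicketStatus",
    "TicketOrigin",
    "Ticket",
    "TicketRegistry",
    "HelpRequest",
    "open_ticket",
    "Assign",
    "Transfer",
    "Resolve",
    "transition_ticket",
    "EmailEvent",
    "throttle_participant_emails",
    "CheerSquad",
    "MilestoneNotification",
    "milestone_events",
    "AdherenceTracker",
]


class FlagCause(enum.Enum):
    MORE_INCORRECT_THAN_CORRECT = "more_incorrect_than_correct"
    ZERO_CORRECT = "zero_correct"
    BELOW_PREDEFINED_LEVEL = "below_predefined_level"
    DECREASE_IN_PERFORMANCE = "decrease_in_performance"
    SESSION_OVERLONG = "session_overlong"
    ABSENCE = "absence"
    ADHERENCE_ESCALATION = "adherence_escalation"


class Severity(enum.Enum):
    RED = "red"
    ORANGE = "orange"


#: Adherence causes are orange; every performance cause and the escalation
#: itself are red.
_ORANGE_CAUSES = frozenset({FlagCause.SESSION_OVERLONG, FlagCause.ABSENCE})


def severity_of(cause: FlagCause) -> Severity:
    return Severity.ORANGE if cause in _ORANGE_CAUSES else Severity.RED


@dataclass(frozen=True)
class Flag:
    participant_id: str
    cause: FlagCause
    source: str
    timestamp: datetime

    @property
    def severity(self) -> Severity:
        return severity_of(self.cause)


@dataclass(frozen=True)
class AdherenceConfig:
    """Thresholds of the flagging and notification rules.

    Defaults are the system's design constants: a >=10% decline flags a
    decrease in performance, sessions over 90 minutes and absences of 72
    hours flag adherence, three orange flags escalate, and automatic
    participant emails are capped at 1 per 72 hours.  ``predefined_levels``
    maps exercise ids to their minimum acceptable raw score; exercises not
    listed use ``default_predefined_level`` (10% of the simulator's native
    maximum score by default).
    """

    decrease_threshold: float = 0.10
    session_duration_limit_min: float = 90.0
    absence_limit_hours: float = 72.0
    orange_escalation_count: int = 3
    email_window_hours: float = 72.0
    email_cap_per_window: int = 1
    predefined_levels: Mapping[str, float] = field(default_factory=dict)
    default_predefined_level: float = 100.0

    def __post_init__(self) -> None:
        positive = (
            self.decrease_threshold,
            self.session_duration_limit_min,
            self.absence_limit_hours,
            self.orange_escalation_count,
            self.email_window_hours,
            self.email_cap_per_window,
        )
        if any(not v > 0 for v in positive):
            raise ValueError("all adherence thresholds must be positive")

    def predefined_level(self, exercise_id: str) -> float:
        return self.predefined_levels.get(exercise_id, self.default_predefined_level)


def evaluate_exercise_flags(
    result: ExerciseResult,
    previous_attempt: ExerciseResult | None,
    config: AdherenceConfig,
) -> list[Flag]:
    """Red performance flags raised by one exercise attempt.

    ``previous_attempt`` must be the same exercise's most recent attempt
    from an earlier session; the decrease rule compares raw scores on the
    exercise's native scale and triggers at exactly a 10% decline
    (``raw <= 0.9 * previous``), provided the previous score was positive.
    Evaluation is pure and total: the same inputs always yield the same
    flags, at most one per cause.
    """
    flags: list[Flag] = []

    def emit(cause: FlagCause) -> None:
        flags.append(
            Flag(
                participant_id=result.participant_id,
                cause=cause,
                source=f"{result.exercise_id}@s{result.session_index}",
                timestamp=result.timestamp,
            )
        )

    if result.n_incorrect > result.n_correct:
        emit(FlagCause.MORE_INCORRECT_THAN_CORRECT)
    if result.n_correct == 0:
        emit(FlagCause.ZERO_CORRECT)
    if result.raw_score < config.predefined_level(result.exercise_id):
        emit(FlagCause.BELOW_PREDEFINED_LEVEL)
    if (
        previous_attempt is not None
        and previous_attempt.raw_score > 0
        and result.raw_score
        <= (1.0 - config.decrease_threshold) * previous_attempt.raw_score
    ):
        emit(FlagCause.DECREASE_IN_PERFORMANCE)
    return flags


def evaluate_session_flags(
    record: SessionRecord,
    previous_session_end: datetime | None,
    config: AdherenceConfig,
) -> list[Flag]:
    """Orange adherence flags raised by one completed session."""
    if record.end < record.start:
        raise MalformedRecordError(
            f"session {record.session_index} ends before it starts"
        )
    flags: list[Flag] = []
    if record.duration_minutes > config.session_duration_limit_min:
        flags.append(
            Flag(
                participant_id=record.participant_id,
                cause=FlagCause.SESSION_OVERLONG,
                source=f"session:{record.session_index}",
                timestamp=record.end,
            )
        )
    if previous_session_end is not None:
        gap_hours = (record.start - previous_session_end).total_seconds() / 3600.0
        if gap_hours >= config.absence_limit_hours:
            flags.append(
                Flag(
                    participant_id=record.participant_id,
                    cause=FlagCause.ABSENCE,
                    source=f"session:{record.session_index}",
                    timestamp=record.start,
                )
            )
    return flags


def escalate(flag_history: Sequence[Flag], config: AdherenceConfig) -> Flag | None:
    """Adherence escalation after every ``orange_escalation_count`` oranges.

    Counts orange flags since the most recent escalation flag in the
    (time-ordered) history; when the count reaches the threshold, returns
    the red escalation flag that the caller should append to the history
    (which resets the counter).
    """
    count = 0
    last: Flag | None = None
    for flag in flag_history:
        if flag.cause is FlagCause.ADHERENCE_ESCALATION:
            count = 0
        elif flag.severity is Severity.ORANGE:
            count += 1
            last = flag
    if count >= config.orange_escalation_count and last is not None:
        return Flag(
            participant_id=last.participant_id,
            cause=FlagCause.ADHERENCE_ESCALATION,
            source=last.source,
            timestamp=last.timestamp,
        )
    return None


# --- tickets -----------------------------------------------------------------


class TicketStatus(enum.Enum):
    OPEN = "open"
    ASSIGNED = "assigned"
    RESOLVED = "resolved"


class TicketOrigin(enum.Enum):
    SYSTEM_FLAG = "system_flag"
    USER_HELP_REQUEST = "user_help_request"


@dataclass(frozen=True)
class HelpRequest:
    """A participant-initiated "I need help" request."""

    participant_id: str
    message: str
    timestamp: datetime


@dataclass
class Ticket:
    id: int
    participant_id: str
    origin: TicketOrigin
    status: TicketStatus = TicketStatus.OPEN
    owner: str | None = None
    thread: list[str] = field(default_factory=list)
    history: list[tuple[str, str | None]] = field(default_factory=list)


@dataclass
class TicketRegistry:
    """Open tickets plus the trainer-alert outbox."""

    tickets: list[Ticket] = field(default_factory=list)
    trainer_alerts: list[str] = field(default_factory=list)
    _next_id: int = 1

    def new_ticket(self, participant_id: str, origin: TicketOrigin) -> Ticket:
        ticket = Ticket(id=self._next_id, participant_id=participant_id, origin=origin)
        self._next_id += 1
        self.tickets.append(ticket)
        self.trainer_alerts.append(
            f"ticket {ticket.id} ({origin.value}) for {participant_id}"
        )
        return ticket


def open_ticket(source: Flag | HelpRequest, registry: TicketRegistry) -> Ticket:
    """Open a trainer ticket from a red flag or a user help request.

    Orange flags never open tickets directly — they only notify, until
    escalation produces a red flag — so passing one raises
    :class:`InvalidFlagError`.  Opening records a trainer alert addressed to
    all trainers.
    """
    if isinstance(source, Flag):
        if source.severity is not Severity.RED:
            raise InvalidFlagError("orange flags notify only; they do not open tickets")
        ticket = registry.new_ticket(source.participant_id, TicketOrigin.SYSTEM_FLAG)
        ticket.thread.append(f"flag {source.cause.value} at {source.source}")
    else:
        ticket = registry.new_ticket(source.participant_id, TicketOrigin.USER_HELP_REQUEST)
        ticket.thread.append(source.message)
    return ticket


@dataclass(frozen=True)
class Assign:
    trainer: str


@dataclass(frozen=True)
class Transfer:
    trainer: str


@dataclass(frozen=True)
class Resolve:
    pass


def transition_ticket(ticket: Ticket, action: Assign | Transfer | Resolve) -> Ticket:
    """Apply one lifecycle action; undefined transitions raise.

    Valid moves: open --assign--> assigned; assigned --assign(same owner)-->
    assigned (idempotent no-op); assigned --transfer--> assigned (handover);
    assigned --resolve--> resolved.  Everything else, including resolving an
    unassigned ticket, is an :class:`InvalidTransitionError`.
    """
    if isinstance(action, Assign):
        if ticket.status is TicketStatus.OPEN:
            ticket.status = TicketStatus.ASSIGNED
            ticket.owner = action.trainer
        elif ticket.status is TicketStatus.ASSIGNED and ticket.owner == action.trainer:
            pass  # idempotent re-assign to the current owner
        else:
            raise InvalidTransitionError(
                f"cannot assign a {ticket.status.value} ticket to {action.trainer!r}"
            )
        ticket.history.append(("assign", action.trainer))
    elif isinstance(action, Transfer):
        if ticket.status is not TicketStatus.ASSIGNED:
            raise InvalidTransitionError(
                f"cannot transfer a {ticket.status.value} ticket"
            )
        ticket.owner = action.trainer
        ticket.history.append(("transfer", action.trainer))
    elif isinstance(action, Resolve):
        if ticket.status is not TicketStatus.ASSIGNED:
            raise InvalidTransitionError(
                f"cannot resolve a {ticket.status.value} ticket"
            )
        ticket.status = TicketStatus.RESOLVED
        ticket.history.append(("resolve", None))
    else:  # pragma: no cover - typing guard
        raise InvalidTransitionError(f"unknown action {action!r}")
    return ticket


# --- participant email throttle ----------------------------------------------


@dataclass(frozen=True)
class EmailEvent:
    participant_id: str
    timestamp: datetime
    reason: str
    emitted: bool


def throttle_participant_emails(
    pending: Sequence[Flag] | Sequence[tuple[datetime, str]],
    config: AdherenceConfig,
    participant_id: str | None = None,
) -> list[EmailEvent]:
    """Apply the 1-per-72-hours cap to a time-ordered stream of email triggers.

    Accepts flags or bare ``(timestamp, reason)`` pairs.  An email is
    emitted only when the previous emission lies at least
    ``email_window_hours`` in the past; suppressed triggers are kept in the
    output with ``emitted=False``.
    """
    window = timedelta(hours=config.email_window_hours)
    out: list[EmailEvent] = []
    last_emitted: datetime | None = None
    prev_ts: datetime | None = None
    for item in pending:
        if isinstance(item, Flag):
            ts, reason, pid = item.timestamp, item.cause.value, item.participant_id
        else:
            ts, reason = item
            pid = participant_id or "participant"
        if prev_ts is not None and ts < prev_ts:
            raise ValueError("email triggers must be time-ordered")
        prev_ts = ts
        ok = last_emitted is None or ts - last_emitted >= window
        if ok:
            last_emitted = ts
        out.append(EmailEvent(participant_id=pid, timestamp=ts, reason=reason, emitted=ok))
    return out


# --- CheerSquad ---------------------------------------------------------------

MAX_SQUAD_SIZE = 5
DEFAULT_MILESTONES: tuple[int, ...] = (1, 10, 20, 30)


@dataclass
class CheerSquad:
    """Up to five friends/family members who cheer training milestones."""

    participant_id: str
    members: list[str] = field(default_factory=list)
    milestones: tuple[int, ...] = DEFAULT_MILESTONES
    invitations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) > MAX_SQUAD_SIZE:
            raise SquadFullError(
                f"a CheerSquad holds at most {MAX_SQUAD_SIZE} members"
            )
        # every registered member is first emailed an invitation
        for member in self.members:
            self.invitations.append(f"invitation to {member}")

    def add_member(self, contact: str) -> None:
        if len(self.members) >= MAX_SQUAD_SIZE:
            raise SquadFullError(
                f"a CheerSquad holds at most {MAX_SQUAD_SIZE} members"
            )
        self.members.append(contact)
        self.invitations.append(f"invitation to {contact}")


@dataclass(frozen=True)
class MilestoneNotification:
    participant_id: str
    member: str
    milestone_session: int
    timestamp: datetime


def milestone_events(state: ModuleState, squad: CheerSquad) -> list[MilestoneNotification]:
    """One notification per squad member at every crossed milestone."""
    events: list[MilestoneNotification] = []
    for milestone in squad.milestones:
        when = state.completed.get(milestone)
        if when is None:
            continue
        for member in squad.members:
            events.append(
                MilestoneNotification(
                    participant_id=state.participant_id,
                    member=member,
                    milestone_session=milestone,
                    timestamp=when,
                )
            )
    return events


# --- stateful tracker used by the engine and simulator ------------------------


class AdherenceTracker:
    """Consumes flags in time order and applies escalation/ticket/email rules.

    Orange flags are recorded and counted toward escalation; red flags (and
    the escalations themselves) open tickets, alert trainers and request a
    throttled automatic participant email.
    """

    def __init__(self, config: AdherenceConfig, registry: TicketRegistry | None = None):
        self.config = config
        self.registry = registry if registry is not None else TicketRegistry()
        self.flags: list[Flag] = []
        self.outbox: list[EmailEvent] = []
        self._last_email: datetime | None = None

    def submit(self, flag: Flag) -> list[Flag]:
        """Record one flag; returns any escalation flag it produced."""
        self.flags.append(flag)
        produced: list[Flag] = []
        if flag.severity is Severity.RED:
            open_ticket(flag, self.registry)
            self._request_email(flag)
        else:
            escalation = escalate(self.flags, self.config)
            if escalation is not None:
                produced.append(escalation)
                produced.extend(self.submit(escalation))
        return produced

    def _request_email(self, flag: Flag) -> None:
        ok = (
            self._last_email is None
            or flag.timestamp - self._last_email
            >= timedelta(hours=self.config.email_window_hours)
        )
        if ok:
            self._last_email = flag.timestamp
        self.outbox.append(
            EmailEvent(
                participant_id=flag.participant_id,
                timestamp=flag.timestamp,
                reason=flag.cause.value,
                emitted=ok,
            )
        )
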