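"""Session composition ("sandwich") and module scheduling.

Each of the 30 sessions in a 10-week module holds 17 exercise slots filled
according to a fixed difficulty pattern: six easy, four medium and seven
hard exercises, with easy exercises opening, relieving the middle of, and
closing the session.  The canonical positional pattern used here is::

    E E M M M H H H E E M H H H H E E      (slots 1..17)

which realizes the stated 2-easy / 3-medium / 3-hard opening and places easy
blocks at the beginning, middle and end.  Easy slots draw from the
participant's strength-tier domains, medium from the mid tier and hard from
the weakness tier; where several exercises qualify for a slot the choice is
pseudorandom, without repeating an exercise within a session.

Sessions 1-12 use the baseline profile; sessions 13-18, 19-24 and 25-30 use
the profile refreshed at their range start.  Sessions cannot be skipped: the
lowest-index uncompleted session remains the only one on offer until it is
completed or the 10-week window closes.  After the module, one booster
session is offered per calendar month.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Callable, Literal, Mapping, Sequence

import numpy as np

from .catalog import CognitiveDomain, ExerciseCatalog, ExerciseSpec, exercises_in_domains
from .errors import SchedulingError, StateError
from .profiles import CognitiveProfile, DifficultyTier, Tier

__all__ = [
    "SESSION_PATTERN",
    "SLOTS_PER_SESSION",
    "SESSIONS_PER_MODULE",
    "MODULE_WINDOW_DAYS",
    "DIFFICULTY_COUNTS",
    "SessionPlan",
    "ModuleState",
    "NextSession",
    "session_rng",
    "make_session_plan",
    "build_module_schedule",
    "next_session",
    "schedule_boosters",
    "profile_epoch_for_session",
]

_E, _M, _H = DifficultyTier.EASY, DifficultyTier.MEDIUM, DifficultyTier.HARD

#: Canonical slot-by-slot difficulty pattern (1-based slots 1..17).
SESSION_PATTERN: tuple[DifficultyTier, ...] = (
    _E, _E, _M, _M, _M, _H, _H, _H, _E, _E, _M, _H, _H, _H, _H, _E, _E,
)

SLOTS_PER_SESSION = 17
SESSIONS_PER_MODULE = 30
#: The 10-week high-intensity module window, anchored at the module start.
MODULE_WINDOW_DAYS = 70

DIFFICULTY_COUNTS: dict[DifficultyTier, int] = {
    _E: 6, _M: 4, _H: 7,
}

_DIFFICULTY_TO_TIER = {
    _E: Tier.STRENGTH, _M: Tier.MID, _H: Tier.WEAKNESS,
}


@dataclass(frozen=True)
class SessionPlan:
    """An ordered list of 17 (exercise, difficulty) slots for one session."""

    session_index: int
    slots: tuple[tuple[ExerciseSpec, DifficultyTier], ...]
    profile_epoch: str

    def __post_init__(self) -> None:
        if len(self.slots) != SLOTS_PER_SESSION:
            raise SchedulingError(
                f"a session plan needs {SLOTS_PER_SESSION} slots, got {len(self.slots)}"
            )

    def difficulty_counts(self) -> dict[DifficultyTier, int]:
        counts = {t: 0 for t in DifficultyTier}
        for _, tier in self.slots:
            counts[tier] += 1
        return counts

    @property
    def exercise_ids(self) -> tuple[str, ...]:
        return tuple(ex.id for ex, _ in self.slots)


@dataclass
class ModuleState:
    """Progress of one participant through a 30-session module."""

    participant_id: str
    start: datetime
    seed: int
    completed: dict[int, datetime] = field(default_factory=dict)

    @property
    def next_index(self) -> int | None:
        """Lowest uncompleted session index, or None when the module is done."""
        for idx in range(1, SESSIONS_PER_MODULE + 1):
            if idx not in self.completed:
                return idx
        return None

    def complete_session(self, session_index: int, when: datetime) -> None:
        expected = self.next_index
        if expected is None:
            raise StateError("all sessions already completed")
        if session_index != expected:
            raise StateError(
                f"sessions complete in order: expected {expected}, got {session_index}"
            )
        self.completed[session_index] = when

    @property
    def window_end(self) -> datetime:
        return self.start + timedelta(days=MODULE_WINDOW_DAYS)


def session_rng(seed: int, session_index: int) -> np.random.Generator:
    """Deterministic random stream for one (module seed, session) pair."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(session_index))))


def make_session_plan(
    profile: CognitiveProfile,
    catalog: ExerciseCatalog,
    session_index: int,
    rng: np.random.Generator | int,
) -> SessionPlan:
    """Fill one session's 17 slots from the profile's tier domains.

    For each difficulty tier the eligible pool is every exercise in the
    matching tier's domains; the needed number is drawn pseudorandomly
    without within-session replacement.  The plan is a pure function of
    (profile, catalog, session_index, rng state).
    """
    if not 1 <= session_index <= SESSIONS_PER_MODULE:
        raise SchedulingError(
            f"session index must be 1..{SESSIONS_PER_MODULE}, got {session_index}"
        )
    if isinstance(rng, (int, np.integer)):
        rng = session_rng(int(rng), session_index)
    drawn: dict[DifficultyTier, list[ExerciseSpec]] = {}
    for difficulty in (_E, _M, _H):
        tier = _DIFFICULTY_TO_TIER[difficulty]
        pool = exercises_in_domains(catalog, profile.domains_in_tier(tier))
        need = DIFFICULTY_COUNTS[difficulty]
        if len(pool) < need:
            raise SchedulingError(
                f"{difficulty.value} slots need {need} distinct exercises but the "
                f"{tier.value} tier offers only {len(pool)}"
            )
        order = rng.permutation(len(pool))[:need]
        drawn[difficulty] = [pool[i] for i in order]
    iters = {t: iter(v) for t, v in drawn.items()}
    slots = tuple((next(iters[t]), t) for t in SESSION_PATTERN)
    return SessionPlan(
        session_index=session_index, slots=slots, profile_epoch=profile.epoch
    )


def profile_epoch_for_session(session_index: int) -> str:
    """Profile epoch a session draws its sandwich from."""
    if session_index >= 25:
        return "refresh-25"
    if session_index >= 19:
        return "refresh-19"
    if session_index >= 13:
        return "refresh-13"
    return "baseline"


ProfileSequence = Mapping[str, CognitiveProfile] | Callable[[str], CognitiveProfile]


def _profile_for(profiles: ProfileSequence, epoch: str) -> CognitiveProfile:
    if callable(profiles):
        return profiles(epoch)
    try:
        return profiles[epoch]
    except KeyError:
        raise SchedulingError(f"no profile available for epoch {epoch!r}") from None


def build_module_schedule(
    state: ModuleState,
    profile_sequence: ProfileSequence,
    catalog: ExerciseCatalog,
    last_session: int = SESSIONS_PER_MODULE,
) -> tuple[SessionPlan, ...]:
    """Plans for sessions 1..last_session under the epoch-appropriate profiles.

    ``profile_sequence`` maps epoch labels ("baseline", "refresh-13",
    "refresh-19", "refresh-25") to profiles, or is a callable computing them
    lazily.  With only a baseline profile supplied, sessions 1-12 can still
    be generated by passing ``last_session=12``.
    """
    plans = []
    for idx in range(1, last_session + 1):
        profile = _profile_for(profile_sequence, profile_epoch_for_session(idx))
        plans.append(make_session_plan(profile, catalog, idx, session_rng(state.seed, idx)))
    return tuple(plans)


@dataclass(frozen=True)
class NextSession:
    """Outcome of asking for the next session: a plan or a blocked status."""

    status: Literal["available", "module_ended", "completed_all"]
    plan: SessionPlan | None = None


def next_session(
    state: ModuleState, now: datetime, schedule: Sequence[SessionPlan]
) -> NextSession:
    """The lowest-index uncompleted session, while the module window is open.

    Asking twice without completing returns the same session: sessions are
    never skipped.  Past the 10-week window the module is closed regardless
    of remaining sessions.
    """
    idx = state.next_index
    if idx is None:
        return NextSession(status="completed_all")
    if now > state.window_end:
        return NextSession(status="module_ended")
    return NextSession(status="available", plan=schedule[idx - 1])


def _add_months(anchor: datetime, months: int) -> datetime:
    month0 = anchor.month - 1 + months
    year = anchor.year + month0 // 12
    month = month0 % 12 + 1
    # clamp the day for short months
    for day in (anchor.day, 30, 29, 28):
        try:
            return anchor.replace(year=year, month=month, day=day)
        except ValueError:
            continue
    raise AssertionError("unreachable")


def schedule_boosters(module_end: datetime, horizon_months: int) -> tuple[datetime, ...]:
    """One booster date per calendar month from the module end to the horizon.

    The post-module follow-up lasts up to 3 years, so ``horizon_months`` may
    not exceed 36.
    """
    if not 0 <= horizon_months <= 36:
        raise ValueError("booster horizon must be between 0 and 36 months")
    return tuple(_add_months(module_end, i) for i in range(1, horizon_months + 1))
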