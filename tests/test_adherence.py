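"""Flag rules and boundaries, escalation, tickets, throttle, CheerSquad."""

import itertools
from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import given, strategies as st

from cogtrain.adherence import (
    AdherenceConfig,
    AdherenceTracker,
    Assign,
    CheerSquad,
    Flag,
    FlagCause,
    HelpRequest,
    Resolve,
    Severity,
    Ticket,
    TicketOrigin,
    TicketRegistry,
    TicketStatus,
    Transfer,
    escalate,
    evaluate_exercise_flags,
    evaluate_session_flags,
    milestone_events,
    open_ticket,
    throttle_participant_emails,
    transition_ticket,
)
from cogtrain.errors import (
    InvalidFlagError,
    InvalidTransitionError,
    MalformedRecordError,
    SquadFullError,
)
from cogtrain.scheduler import ModuleState
from cogtrain.scoring import ExerciseResult, SessionRecord

from conftest import T0

CFG = AdherenceConfig()


def _result(n_correct=10, n_incorrect=0, raw=500.0, session=2, ts=T0):
    return ExerciseResult(
        participant_id="p1", exercise_id="eagle_eye", session_index=session,
        timestamp=ts, n_correct=n_correct, n_incorrect=n_incorrect,
        raw_score=raw, duration_s=100,
    )


def _causes(flags):
    return {f.cause for f in flags}


# --- exercise (red) flag rules ------------------------------------------------


def test_more_incorrect_than_correct_flags():
    flags = evaluate_exercise_flags(_result(n_correct=3, n_incorrect=5), None, CFG)
    assert FlagCause.MORE_INCORRECT_THAN_CORRECT in _causes(flags)
    assert all(f.severity is Severity.RED for f in flags)


def test_equal_counts_do_not_flag():
    flags = evaluate_exercise_flags(_result(n_correct=4, n_incorrect=4), None, CFG)
    assert FlagCause.MORE_INCORRECT_THAN_CORRECT not in _causes(flags)


def test_zero_correct_flags():
    flags = evaluate_exercise_flags(_result(n_correct=0, n_incorrect=1), None, CFG)
    assert FlagCause.ZERO_CORRECT in _causes(flags)


def test_below_predefined_level_flags():
    # default level is 100 (10% of the native maximum)
    low = evaluate_exercise_flags(_result(raw=99.0), None, CFG)
    ok = evaluate_exercise_flags(_result(raw=100.0), None, CFG)
    assert FlagCause.BELOW_PREDEFINED_LEVEL in _causes(low)
    assert FlagCause.BELOW_PREDEFINED_LEVEL not in _causes(ok)


@pytest.mark.parametrize(
    "current, flagged", [(90.0, True), (89.0, True), (90.0001, False), (91.0, False)]
)
def test_decrease_flag_boundary_is_exactly_ten_percent(current, flagged):
    prev = _result(raw=100.0, session=1)
    flags = evaluate_exercise_flags(_result(raw=current, session=2), prev, CFG)
    assert (FlagCause.DECREASE_IN_PERFORMANCE in _causes(flags)) is flagged


@given(current=st.floats(50.0, 130.0))
def test_decrease_boundary_bisection(current):
    """The rule triggers iff the decline is >= 10% of the previous score."""
    prev = _result(raw=100.0, session=1)
    flags = evaluate_exercise_flags(_result(raw=current, session=2), prev, CFG)
    assert (FlagCause.DECREASE_IN_PERFORMANCE in _causes(flags)) is (current <= 90.0)


def test_clean_pass_raises_no_flags():
    flags = evaluate_exercise_flags(_result(n_correct=10, n_incorrect=0, raw=500.0), None, CFG)
    assert flags == []


def test_flag_evaluation_is_pure_and_deduplicated():
    result = _result(n_correct=0, n_incorrect=5, raw=10.0)
    a = evaluate_exercise_flags(result, None, CFG)
    b = evaluate_exercise_flags(result, None, CFG)
    assert a == b
    assert len({(f.cause, f.source) for f in a}) == len(a)


# --- session (orange) flag rules ----------------------------------------------


def _record(duration_min, start=T0):
    return SessionRecord(
        participant_id="p1", session_index=2, start=start,
        end=start + timedelta(minutes=duration_min),
    )


@pytest.mark.parametrize("minutes, flagged", [(91, True), (90, False), (90.5, True)])
def test_overlong_session_boundary_is_strict_at_90_minutes(minutes, flagged):
    flags = evaluate_session_flags(_record(minutes), None, CFG)
    assert (FlagCause.SESSION_OVERLONG in _causes(flags)) is flagged
    assert all(f.severity is Severity.ORANGE for f in flags)


@pytest.mark.parametrize("gap_hours, flagged", [(72, True), (71.99, False), (100, True)])
def test_absence_boundary_is_inclusive_at_72_hours(gap_hours, flagged):
    prev_end = T0
    record = _record(45, start=prev_end + timedelta(hours=gap_hours))
    flags = evaluate_session_flags(record, prev_end, CFG)
    assert (FlagCause.ABSENCE in _causes(flags)) is flagged


def test_first_session_has_no_absence_gap():
    assert evaluate_session_flags(_record(45), None, CFG) == []


def test_session_ending_before_it_starts_is_malformed():
    record = SessionRecord(
        participant_id="p1", session_index=1, start=T0, end=T0 - timedelta(minutes=1)
    )
    with pytest.raises(MalformedRecordError):
        evaluate_session_flags(record, None, CFG)


# --- escalation ---------------------------------------------------------------


def _orange(i):
    return Flag(
        participant_id="p1", cause=FlagCause.ABSENCE, source=f"session:{i}",
        timestamp=T0 + timedelta(hours=i),
    )


def test_third_orange_escalates_to_red():
    history = [_orange(i) for i in range(3)]
    flag = escalate(history, CFG)
    assert flag is not None
    assert flag.cause is FlagCause.ADHERENCE_ESCALATION
    assert flag.severity is Severity.RED


def test_two_oranges_do_not_escalate():
    assert escalate([_orange(0), _orange(1)], CFG) is None


def test_six_oranges_give_exactly_two_escalations():
    """Counting oracle with reset: escalations = floor(oranges / 3)."""
    tracker = AdherenceTracker(CFG)
    produced = []
    for i in range(6):
        produced.extend(tracker.submit(_orange(i)))
    assert len(produced) == 2
    assert all(f.cause is FlagCause.ADHERENCE_ESCALATION for f in produced)
    # oracle over a longer run
    tracker2 = AdherenceTracker(CFG)
    total = sum(len(tracker2.submit(_orange(i))) for i in range(20))
    assert total == 20 // 3


# --- tickets ------------------------------------------------------------------


def _red():
    return Flag(
        participant_id="p1", cause=FlagCause.ZERO_CORRECT, source="eagle_eye@s2",
        timestamp=T0,
    )


def test_red_flag_opens_a_system_ticket_and_alerts_trainers():
    registry = TicketRegistry()
    ticket = open_ticket(_red(), registry)
    assert ticket.origin is TicketOrigin.SYSTEM_FLAG
    assert ticket.status is TicketStatus.OPEN
    assert len(registry.trainer_alerts) == 1


def test_help_request_opens_a_user_ticket():
    registry = TicketRegistry()
    ticket = open_ticket(
        HelpRequest(participant_id="p1", message="I need help", timestamp=T0), registry
    )
    assert ticket.origin is TicketOrigin.USER_HELP_REQUEST


def test_orange_flag_does_not_open_a_ticket():
    with pytest.raises(InvalidFlagError):
        open_ticket(_orange(0), TicketRegistry())


def test_ticket_lifecycle_happy_path():
    registry = TicketRegistry()
    ticket = open_ticket(_red(), registry)
    transition_ticket(ticket, Assign("T1"))
    assert (ticket.status, ticket.owner) == (TicketStatus.ASSIGNED, "T1")
    transition_ticket(ticket, Transfer("T2"))
    assert (ticket.status, ticket.owner) == (TicketStatus.ASSIGNED, "T2")
    transition_ticket(ticket, Resolve())
    assert ticket.status is TicketStatus.RESOLVED
    assert [h[0] for h in ticket.history] == ["assign", "transfer", "resolve"]


def test_resolving_an_unassigned_ticket_is_invalid():
    ticket = open_ticket(_red(), TicketRegistry())
    with pytest.raises(InvalidTransitionError):
        transition_ticket(ticket, Resolve())


def test_reassigning_the_same_trainer_is_idempotent():
    ticket = open_ticket(_red(), TicketRegistry())
    transition_ticket(ticket, Assign("T1"))
    transition_ticket(ticket, Assign("T1"))
    assert (ticket.status, ticket.owner) == (TicketStatus.ASSIGNED, "T1")


def test_state_machine_is_closed_under_all_short_action_sequences():
    """Exhaustive model check: every action sequence either raises cleanly
    or lands in a consistent (status, owner) state."""
    actions = [Assign("T1"), Assign("T2"), Transfer("T1"), Transfer("T2"), Resolve()]
    for length in range(1, 5):
        for seq in itertools.product(actions, repeat=length):
            ticket = Ticket(id=1, participant_id="p1", origin=TicketOrigin.SYSTEM_FLAG)
            for action in seq:
                try:
                    transition_ticket(ticket, action)
                except InvalidTransitionError:
                    pass
                assert ticket.status in TicketStatus
                if ticket.status is TicketStatus.OPEN:
                    assert ticket.owner is None
                else:
                    assert ticket.owner in ("T1", "T2")


# --- email throttle -----------------------------------------------------------


def _triggers(hours):
    return [(T0 + timedelta(hours=h), "red_flag") for h in hours]


def test_throttle_emits_at_0_and_80_hours_only():
    events = throttle_participant_emails(_triggers([0, 10, 80]), CFG)
    assert [e.emitted for e in events] == [True, False, True]


def test_single_event_is_emitted():
    events = throttle_participant_emails(_triggers([5]), CFG)
    assert [e.emitted for e in events] == [True]


def test_no_72h_window_holds_more_than_one_email():
    events = throttle_participant_emails(_triggers(range(240)), CFG)
    emitted = [e.timestamp for e in events if e.emitted]
    window = timedelta(hours=CFG.email_window_hours)
    # sliding-window oracle: count emissions in [t, t + 72 h) for every start
    for start in emitted:
        inside = [t for t in emitted if start <= t < start + window]
        assert len(inside) <= CFG.email_cap_per_window
    assert len(emitted) == 4  # 0, 72, 144, 216


def test_unordered_triggers_are_rejected():
    with pytest.raises(ValueError):
        throttle_participant_emails(_triggers([5, 1]), CFG)


# --- CheerSquad ---------------------------------------------------------------


def test_squad_accepts_five_members_and_rejects_the_sixth():
    squad = CheerSquad(participant_id="p1")
    for i in range(5):
        squad.add_member(f"friend{i}")
    assert len(squad.members) == 5
    assert len(squad.invitations) == 5  # each member is first invited
    with pytest.raises(SquadFullError):
        squad.add_member("friend5")


def test_milestones_notify_every_member_at_every_crossing():
    state = ModuleState(participant_id="p1", start=T0, seed=0)
    for idx in range(1, 31):
        state.complete_session(idx, T0 + timedelta(days=2 * idx))
    squad = CheerSquad(participant_id="p1", members=[f"m{i}" for i in range(5)])
    events = milestone_events(state, squad)
    # default milestones: sessions 1, 10, 20, 30 -> 4 crossings x 5 members
    assert len(events) == 20
    assert {e.milestone_session for e in events} == {1, 10, 20, 30}


def test_empty_squad_notifies_nobody():
    state = ModuleState(participant_id="p1", start=T0, seed=0)
    state.complete_session(1, T0)
    assert milestone_events(state, CheerSquad(participant_id="p1")) == []


def test_uncrossed_milestones_are_silent():
    state = ModuleState(participant_id="p1", start=T0, seed=0)
    state.complete_session(1, T0)
    squad = CheerSquad(participant_id="p1", members=["m0"])
    events = milestone_events(state, squad)
    assert [e.milestone_session for e in events] == [1]


def test_config_defaults_are_the_design_constants():
    cfg = AdherenceConfig()
    assert cfg.decrease_threshold == 0.10
    assert cfg.session_duration_limit_min == 90.0
    assert cfg.absence_limit_hours == 72.0
    assert cfg.orange_escalation_count == 3
    assert cfg.email_window_hours == 72.0
    assert cfg.email_cap_per_window == 1
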