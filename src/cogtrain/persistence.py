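"""Versioned save/load of engine and participant state.

State files are JSON (schema version "1"), self-contained: they carry the
catalog, normative reference, cohort distributions, engine configuration
and the full participant history (profiles, module progress, attempts,
flags, tickets, outbox).  Timestamps are ISO 8601; session indices are
1-based throughout.  Loading a file written by ``save_state`` restores a
state from which all subsequent plans are identical to an uninterrupted
run, because plan randomness is a pure function of (module seed, session
index).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime
from pathlib import Path

from .adherence import (
    AdherenceConfig,
    AdherenceTracker,
    CheerSquad,
    EmailEvent,
    Flag,
    FlagCause,
    MilestoneNotification,
    Ticket,
    TicketOrigin,
    TicketRegistry,
    TicketStatus,
)
from .catalog import CognitiveDomain, ExerciseCatalog, load_catalog
from .config import EngineConfig
from .engine import ParticipantState, TrainingEngine
from .errors import StateLoadError, StateVersionError
from .profiles import CognitiveProfile, NormativeReference
from .scheduler import ModuleState
from .scoring import ExerciseCohortStats, ExerciseResult, SessionRecord

__all__ = ["STATE_VERSION", "save_state", "load_state", "state_to_dict", "state_from_dict"]

STATE_VERSION = "1"


def _ts(dt: datetime) -> str:
    return dt.isoformat()


def _dt(s: str) -> datetime:
    return datetime.fromisoformat(s)


def _result_to_dict(r: ExerciseResult) -> dict:
    d = asdict(r)
    d["timestamp"] = _ts(r.timestamp)
    return d


def _result_from_dict(d: dict) -> ExerciseResult:
    d = dict(d)
    d["timestamp"] = _dt(d["timestamp"])
    return ExerciseResult(**d)


def _record_to_dict(rec: SessionRecord) -> dict:
    return {
        "participant_id": rec.participant_id,
        "session_index": rec.session_index,
        "start": _ts(rec.start),
        "end": _ts(rec.end),
        "results": [_result_to_dict(r) for r in rec.results],
    }


def _record_from_dict(d: dict) -> SessionRecord:
    return SessionRecord(
        participant_id=d["participant_id"],
        session_index=d["session_index"],
        start=_dt(d["start"]),
        end=_dt(d["end"]),
        results=tuple(_result_from_dict(r) for r in d["results"]),
    )


def _flag_to_dict(f: Flag) -> dict:
    return {
        "participant_id": f.participant_id,
        "cause": f.cause.value,
        "source": f.source,
        "timestamp": _ts(f.timestamp),
    }


def _flag_from_dict(d: dict) -> Flag:
    return Flag(
        participant_id=d["participant_id"],
        cause=FlagCause(d["cause"]),
        source=d["source"],
        timestamp=_dt(d["timestamp"]),
    )


def _tracker_to_dict(t: AdherenceTracker) -> dict:
    return {
        "flags": [_flag_to_dict(f) for f in t.flags],
        "outbox": [
            {
                "participant_id": e.participant_id,
                "timestamp": _ts(e.timestamp),
                "reason": e.reason,
                "emitted": e.emitted,
            }
            for e in t.outbox
        ],
        "last_email": _ts(t._last_email) if t._last_email else None,
        "registry": {
            "next_id": t.registry._next_id,
            "trainer_alerts": list(t.registry.trainer_alerts),
            "tickets": [
                {
                    "id": tk.id,
                    "participant_id": tk.participant_id,
                    "origin": tk.origin.value,
                    "status": tk.status.value,
                    "owner": tk.owner,
                    "thread": list(tk.thread),
                    "history": [list(h) for h in tk.history],
                }
                for tk in t.registry.tickets
            ],
        },
    }


def _tracker_from_dict(d: dict, config: AdherenceConfig) -> AdherenceTracker:
    registry = TicketRegistry(
        tickets=[
            Ticket(
                id=tk["id"],
                participant_id=tk["participant_id"],
                origin=TicketOrigin(tk["origin"]),
                status=TicketStatus(tk["status"]),
                owner=tk["owner"],
                thread=list(tk["thread"]),
                history=[tuple(h) for h in tk["history"]],
            )
            for tk in d["registry"]["tickets"]
        ],
        trainer_alerts=list(d["registry"]["trainer_alerts"]),
        _next_id=d["registry"]["next_id"],
    )
    tracker = AdherenceTracker(config, registry)
    tracker.flags = [_flag_from_dict(f) for f in d["flags"]]
    tracker.outbox = [
        EmailEvent(
            participant_id=e["participant_id"],
            timestamp=_dt(e["timestamp"]),
            reason=e["reason"],
            emitted=e["emitted"],
        )
        for e in d["outbox"]
    ]
    tracker._last_email = _dt(d["last_email"]) if d["last_email"] else None
    return tracker


def state_to_dict(engine: TrainingEngine, state: ParticipantState) -> dict:
    """Serialize the engine bundle plus one participant's full state."""
    adherence = asdict(engine.config.adherence)
    adherence["predefined_levels"] = dict(adherence["predefined_levels"])
    return {
        "version": STATE_VERSION,
        "catalog": {
            "exercises": [
                {"id": e.id, "name": e.display_name, "domain": e.domain.value}
                for e in engine.catalog.exercises
            ],
            "assessments": [
                {"id": a.id, "domain": a.domain.value, "source": a.source_name}
                for a in engine.catalog.assessments
            ],
        },
        "norms": {
            "stats": {k: list(v) for k, v in engine.norms.stats.items()},
            "provenance": engine.norms.provenance,
        },
        "cohort_stats": {
            "stats": {k: list(v) for k, v in engine.cohort_stats.as_dict().items()},
            "provenance": engine.cohort_stats.provenance,
        },
        "adherence_config": adherence,
        "engine_seed": engine.config.seed,
        "participant": {
            "id": state.participant_id,
            "profiles": {
                epoch: {d.value: z for d, z in p.domain_z.items()}
                for epoch, p in state.profiles.items()
            },
            "module": {
                "start": _ts(state.module.start),
                "seed": state.module.seed,
                "completed": {str(k): _ts(v) for k, v in state.module.completed.items()},
            },
            "records": [_record_to_dict(r) for r in state.records],
            "attempt_counts": dict(state.attempt_counts),
            "last_attempt": {
                k: _result_to_dict(v) for k, v in state.last_attempt.items()
            },
            "tracker": _tracker_to_dict(state.tracker),
            "squad": (
                {
                    "members": list(state.squad.members),
                    "milestones": list(state.squad.milestones),
                }
                if state.squad
                else None
            ),
            "notifications": [
                {
                    "member": n.member,
                    "milestone_session": n.milestone_session,
                    "timestamp": _ts(n.timestamp),
                }
                for n in state.notifications
            ],
        },
    }


def state_from_dict(data: dict) -> tuple[TrainingEngine, ParticipantState]:
    if data.get("version") != STATE_VERSION:
        raise StateVersionError(
            f"unsupported state version {data.get('version')!r}; "
            f"this build reads version {STATE_VERSION!r}"
        )
    catalog = load_catalog(data["catalog"])
    norms = NormativeReference(
        stats={k: tuple(v) for k, v in data["norms"]["stats"].items()},
        provenance=data["norms"]["provenance"],
    )
    cohort = ExerciseCohortStats(
        {k: tuple(v) for k, v in data["cohort_stats"]["stats"].items()},
        provenance=data["cohort_stats"]["provenance"],
    )
    adherence = AdherenceConfig(**data["adherence_config"])
    config = EngineConfig(adherence=adherence, seed=data["engine_seed"])
    engine = TrainingEngine(catalog, norms, cohort, config)

    pdata = data["participant"]
    profiles = {
        epoch: CognitiveProfile.from_scores(
            pdata["id"], epoch, {CognitiveDomain(k): v for k, v in zs.items()}
        )
        for epoch, zs in pdata["profiles"].items()
    }
    module = ModuleState(
        participant_id=pdata["id"],
        start=_dt(pdata["module"]["start"]),
        seed=pdata["module"]["seed"],
        completed={int(k): _dt(v) for k, v in pdata["module"]["completed"].items()},
    )
    squad = None
    if pdata["squad"] is not None:
        squad = CheerSquad(
            participant_id=pdata["id"],
            members=list(pdata["squad"]["members"]),
            milestones=tuple(pdata["squad"]["milestones"]),
        )
    state = ParticipantState(
        participant_id=pdata["id"],
        profiles=profiles,
        module=module,
        tracker=_tracker_from_dict(pdata["tracker"], adherence),
        records=[_record_from_dict(r) for r in pdata["records"]],
        attempt_counts=dict(pdata["attempt_counts"]),
        last_attempt={
            k: _result_from_dict(v) for k, v in pdata["last_attempt"].items()
        },
        squad=squad,
        notifications=[
            MilestoneNotification(
                participant_id=pdata["id"],
                member=n["member"],
                milestone_session=n["milestone_session"],
                timestamp=_dt(n["timestamp"]),
            )
            for n in pdata["notifications"]
        ],
    )
    return engine, state


def save_state(path: str | Path, engine: TrainingEngine, state: ParticipantState) -> None:
    payload = json.dumps(state_to_dict(engine, state), indent=1)
    Path(path).write_text(payload, encoding="utf-8")


def load_state(path: str | Path) -> tuple[TrainingEngine, ParticipantState]:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise StateLoadError(f"cannot parse state file {path}: {exc}") from exc
    return state_from_dict(data)
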