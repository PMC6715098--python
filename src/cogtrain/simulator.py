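"""Virtual participants and synthetic cohorts.

No trial data ship with this package; everything downstream is exercised
against simulated participants.  A virtual participant has a latent ability
per cognitive domain (in population-SD units), a per-domain learning rate
capturing practice gains per attempt, attempt-level performance noise, and
behavioral traits: session cadence, a probability of overlong sessions and
a probability of lapses (gaps of 72 h or more).

Raw exercise scores live on a bounded native scale shared by all simulated
exercises: ``raw = clip(500 + 150 * perf, 0, 1000)`` where ``perf`` is the
latent performance (ability + practice + noise).  Correct/incorrect counts
are drawn from 20 Bernoulli trials with success probability
``sigmoid(perf)``, so higher scores come with higher correct fractions.

All randomness flows from seeded :class:`numpy.random.Generator` streams;
identical parameters and seed reproduce identical logs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import DOMAINS, CognitiveDomain, ExerciseCatalog, ExerciseSpec, default_catalog
from .engine import ParticipantState, TrainingEngine
from .profiles import NormativeReference
from .scoring import (
    DomainScoreBoard,
    ExerciseCohortStats,
    ExerciseResult,
    SessionRecord,
    build_score_board,
)

__all__ = [
    "RAW_SCORE_BASE",
    "RAW_SCORE_SCALE",
    "RAW_SCORE_MAX",
    "TRIALS_PER_ATTEMPT",
    "VirtualParticipant",
    "SimulationLog",
    "generate_normative_cohort",
    "simulate_attempt",
    "simulate_module",
    "simulate_scoreboard_cohort",
    "Scenario",
    "load_scenario",
    "simulate_cohort",
]

RAW_SCORE_BASE = 500.0
RAW_SCORE_SCALE = 150.0
RAW_SCORE_MAX = 1000.0
TRIALS_PER_ATTEMPT = 20

#: Mean inter-session gap for a 3-sessions-per-week cadence (168 h / 3).
DEFAULT_GAP_HOURS = 56.0

_EPOCH_START = datetime(2024, 1, 1, 9, 0, tzinfo=timezone.utc)


def _raw_from_perf(perf: np.ndarray | float) -> np.ndarray | float:
    return np.clip(RAW_SCORE_BASE + RAW_SCORE_SCALE * np.asarray(perf), 0.0, RAW_SCORE_MAX)


@dataclass(frozen=True)
class VirtualParticipant:
    """Latent abilities and behavioral traits of one simulated participant."""

    id: str
    latent_ability: Mapping[CognitiveDomain, float]
    learning_rate: Mapping[CognitiveDomain, float] = field(
        default_factory=lambda: {d: 0.02 for d in DOMAINS}
    )
    performance_noise_sd: float = 0.3
    gap_hours_mean: float = DEFAULT_GAP_HOURS
    gap_hours_sd: float = 12.0
    overlong_prob: float = 0.05
    lapse_prob: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.overlong_prob, self.lapse_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.performance_noise_sd < 0:
            raise ValueError("performance noise SD must be non-negative")

    def perf(self, domain: CognitiveDomain, attempt_number: int) -> float:
        """Noise-free latent performance at a given attempt."""
        return (
            self.latent_ability[domain]
            + self.learning_rate[domain] * (attempt_number - 1)
        )


def generate_normative_cohort(
    n: int = 100,
    seed: int = 0,
    catalog: ExerciseCatalog | None = None,
    ability_sd: float = 1.0,
    test_noise_sd: float = 0.3,
) -> tuple[NormativeReference, ExerciseCohortStats]:
    """Simulate a pilot-style reference cohort (default n=100).

    Returns the per-assessment normative means/SDs used to standardize
    intake tests and the per-exercise first-attempt score distributions
    used as the comparison reference for training scores.
    """
    if n < 2:
        raise ValueError("a normative cohort needs at least 2 participants")
    catalog = catalog if catalog is not None else default_catalog()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 715517)))
    abilities = ability_sd * rng.standard_normal((n, len(DOMAINS)))
    ass_stats: dict[str, tuple[float, float]] = {}
    for assessment in catalog.assessments:
        col = abilities[:, assessment.domain.canonical_index]
        scores = col + test_noise_sd * rng.standard_normal(n)
        ass_stats[assessment.id] = (float(scores.mean()), float(scores.std(ddof=1)))
    ex_stats: dict[str, tuple[float, float]] = {}
    for ex in catalog.exercises:
        col = abilities[:, ex.domain.canonical_index]
        raw = _raw_from_perf(col + test_noise_sd * rng.standard_normal(n))
        ex_stats[ex.id] = (float(raw.mean()), float(raw.std(ddof=1)))
    provenance = f"pilot-simulated, seed {seed}, n={n}"
    return (
        NormativeReference(stats=ass_stats, provenance=provenance),
        ExerciseCohortStats(ex_stats, provenance=provenance),
    )


def simulate_attempt(
    p: VirtualParticipant,
    exercise: ExerciseSpec,
    attempt_number: int,
    rng: np.random.Generator,
    session_index: int = 1,
    timestamp: datetime | None = None,
) -> ExerciseResult:
    """One noisy attempt: ability + practice gain + noise on the native scale."""
    perf = p.perf(exercise.domain, attempt_number) + (
        p.performance_noise_sd * rng.standard_normal() if p.performance_noise_sd else 0.0
    )
    raw = float(_raw_from_perf(perf))
    p_correct = 1.0 / (1.0 + np.exp(-perf))
    n_correct = int(rng.binomial(TRIALS_PER_ATTEMPT, p_correct))
    duration = float(max(30.0, rng.normal(150.0, 30.0)))
    return ExerciseResult(
        participant_id=p.id,
        exercise_id=exercise.id,
        session_index=session_index,
        timestamp=timestamp if timestamp is not None else _EPOCH_START,
        n_correct=n_correct,
        n_incorrect=TRIALS_PER_ATTEMPT - n_correct,
        raw_score=raw,
        duration_s=duration,
    )


@dataclass
class SimulationLog:
    """Complete, reproducible record of one simulated module."""

    participant: VirtualParticipant
    seed: int
    state: ParticipantState
    sessions_completed: int

    @property
    def results(self) -> list[ExerciseResult]:
        return [r for rec in self.state.records for r in rec.results]

    @property
    def flags(self):
        return self.state.tracker.flags

    @property
    def tickets(self):
        return self.state.tracker.registry.tickets

    @property
    def emails(self):
        return self.state.tracker.outbox

    def summary(self) -> dict[str, int]:
        return {
            "sessions": self.sessions_completed,
            "attempts": len(self.results),
            "flags": len(self.flags),
            "tickets": len(self.tickets),
            "emails_emitted": sum(e.emitted for e in self.emails),
        }


def _intake_scores(
    p: VirtualParticipant, engine: TrainingEngine, rng: np.random.Generator
) -> dict[str, float]:
    scores: dict[str, float] = {}
    for assessment in engine.catalog.assessments:
        noise = p.performance_noise_sd * rng.standard_normal() if p.performance_noise_sd else 0.0
        scores[assessment.id] = p.latent_ability[assessment.domain] + noise
    return scores


def simulate_module(
    p: VirtualParticipant,
    engine: TrainingEngine,
    rng: np.random.Generator | None = None,
    start: datetime | None = None,
) -> SimulationLog:
    """Run one participant through intake and up to 30 sessions.

    Session gaps, durations and lapses follow the participant's traits;
    the engine evaluates flags, escalations, emails and profile refreshes
    exactly as it would for real data.  Ends early if the 10-week window
    closes before all sessions complete.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((int(p.seed), 6078770)))
    start = start if start is not None else _EPOCH_START
    state = engine.intake(p.id, _intake_scores(p, engine, rng), start, seed=p.seed)
    now = start
    completed = 0
    while True:
        offer = engine.next_plan(state, now)
        if offer.status != "available":
            break
        plan = offer.plan
        assert plan is not None
        if rng.random() < p.overlong_prob:
            duration_min = 91.0 + rng.exponential(10.0)
        else:
            duration_min = float(np.clip(rng.normal(45.0, 8.0), 20.0, 89.0))
        session_start = now
        session_end = session_start + timedelta(minutes=duration_min)
        step = timedelta(minutes=duration_min / len(plan.slots))
        results = []
        for i, (exercise, _tier) in enumerate(plan.slots):
            results.append(
                simulate_attempt(
                    p,
                    exercise,
                    state.attempt_number(exercise.id),
                    rng,
                    session_index=plan.session_index,
                    timestamp=session_start + (i + 1) * step,
                )
            )
        record = SessionRecord(
            participant_id=p.id,
            session_index=plan.session_index,
            start=session_start,
            end=session_end,
            results=tuple(results),
        )
        engine.record_session(state, record)
        completed += 1
        if rng.random() < p.lapse_prob:
            gap_hours = 72.0 + rng.exponential(24.0)
        else:
            gap_hours = float(np.clip(rng.normal(p.gap_hours_mean, p.gap_hours_sd), 4.0, 71.0))
        now = session_end + timedelta(hours=gap_hours)
    return SimulationLog(
        participant=p, seed=p.seed, state=state, sessions_completed=completed
    )


def simulate_scoreboard_cohort(
    n: int,
    seed: int = 0,
    catalog: ExerciseCatalog | None = None,
    ability_sd: float = 1.0,
    noise_sd: float = 0.3,
) -> DomainScoreBoard:
    """Domain score board for ``n`` participants, one attempt per exercise.

    The comparison distributions are estimated from the same cohort, so this
    is the configuration under which the feedback target zone should flag
    close to 25% of participants per domain.  Vectorized for large n.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 participants")
    catalog = catalog if catalog is not None else default_catalog()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 260273)))
    abilities = ability_sd * rng.standard_normal((n, len(DOMAINS)))
    pid_width = len(str(n - 1))
    pids = np.array([f"p{i:0{pid_width}d}" for i in range(n)])
    frames = []
    for ex in catalog.exercises:
        perf = abilities[:, ex.domain.canonical_index] + noise_sd * rng.standard_normal(n)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pids,
                    "exercise_id": ex.id,
                    "session_index": 1,
                    "raw_score": _raw_from_perf(perf),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    stats = ExerciseCohortStats.from_results(df, provenance=f"simulated cohort n={n}")
    return build_score_board(df, catalog, stats)


# --- scenario files -----------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """A structured-text description of a simulated cohort."""

    name: str
    n_participants: int
    seed: int
    norms_n: int = 100
    ability_sd: float = 1.0
    test_noise_sd: float = 0.3
    learning_rate_mean: float = 0.02
    learning_rate_sd: float = 0.01
    performance_noise_sd: float = 0.3
    gap_hours_mean: float = DEFAULT_GAP_HOURS
    gap_hours_sd: float = 12.0
    overlong_prob: float = 0.05
    lapse_prob: float = 0.10


def load_scenario(source: str | Path | Mapping) -> Scenario:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    return Scenario(**data)


def draw_participant(
    scenario: Scenario, index: int, rng: np.random.Generator
) -> VirtualParticipant:
    abilities = {
        d: float(scenario.ability_sd * rng.standard_normal()) for d in DOMAINS
    }
    rates = {
        d: float(
            abs(rng.normal(scenario.learning_rate_mean, scenario.learning_rate_sd))
        )
        for d in DOMAINS
    }
    return VirtualParticipant(
        id=f"{scenario.name}-{index:04d}",
        latent_ability=abilities,
        learning_rate=rates,
        performance_noise_sd=scenario.performance_noise_sd,
        gap_hours_mean=scenario.gap_hours_mean,
        gap_hours_sd=scenario.gap_hours_sd,
        overlong_prob=scenario.overlong_prob,
        lapse_prob=scenario.lapse_prob,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def simulate_cohort(
    scenario: Scenario,
    catalog: ExerciseCatalog | None = None,
    seed: int | None = None,
) -> tuple[TrainingEngine, list[SimulationLog]]:
    """Run a whole scenario: norms, engine, one simulated module per participant."""
    catalog = catalog if catalog is not None else default_catalog()
    root_seed = scenario.seed if seed is None else seed
    norms, stats = generate_normative_cohort(
        scenario.norms_n,
        seed=root_seed,
        catalog=catalog,
        ability_sd=scenario.ability_sd,
        test_noise_sd=scenario.test_noise_sd,
    )
    engine = TrainingEngine(catalog, norms, stats)
    rng = np.random.default_rng(np.random.SeedSequence((int(root_seed), 535345)))
    logs = []
    for i in range(scenario.n_participants):
        participant = draw_participant(scenario, i, rng)
        logs.append(simulate_module(participant, engine))
    return engine, logs
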