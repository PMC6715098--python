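"""Comparable scoring, domain aggregation and performance feedback.

Raw exercise scores live on exercise-native scales and cannot be compared
directly.  They are made comparable by standardizing each score against the
cohort's score distribution for that exercise (a z-score), then averaged at
the cognitive-domain level.  Feedback shows, per domain, the participant's
domain score against a *target zone*: the band at or above the cohort's 75th
percentile, i.e. the top performing 25%.

Conventions pinned here (and relied on by tests):

* the target-zone bound is the linear-interpolation 75th percentile of the
  cohort's domain scores (``numpy.quantile`` default);
* a participant is *in zone* when their score is greater than or equal to
  the bound, so in a cohort of n distinct scores either ``floor(0.25 n)`` or
  ``ceil(0.25 n)`` participants are in zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import CognitiveDomain, ExerciseCatalog
from .errors import (
    DegenerateDistributionError,
    InsufficientCohortError,
    MalformedRecordError,
    UnknownExerciseError,
)

__all__ = [
    "ExerciseResult",
    "SessionRecord",
    "ExerciseCohortStats",
    "comparable_score",
    "domain_scores",
    "DomainScoreBoard",
    "build_score_board",
    "FeedbackBar",
    "feedback_graph",
    "TARGET_ZONE_QUANTILE",
]

#: Cohort quantile defining the lower edge of the feedback target zone
#: (top performing 25%).
TARGET_ZONE_QUANTILE = 0.75

#: Minimum cohort size for which a target zone is computed.
DEFAULT_MIN_COHORT = 20


@dataclass(frozen=True)
class ExerciseResult:
    """Outcome of one attempt at one exercise."""

    participant_id: str
    exercise_id: str
    session_index: int
    timestamp: datetime
    n_correct: int
    n_incorrect: int
    raw_score: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.n_correct < 0 or self.n_incorrect < 0:
            raise ValueError("response counts must be non-negative")
        if self.duration_s < 0:
            raise ValueError("duration must be non-negative")


@dataclass(frozen=True)
class SessionRecord:
    """One completed training session with its per-exercise results."""

    participant_id: str
    session_index: int
    start: datetime
    end: datetime
    results: tuple[ExerciseResult, ...] = ()

    def validate(self) -> None:
        if self.end < self.start:
            raise MalformedRecordError(
                f"session {self.session_index} ends before it starts"
            )

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


class ExerciseCohortStats:
    """Per-exercise location/scale of the comparison cohort's raw scores."""

    def __init__(self, stats: Mapping[str, tuple[float, float]], provenance: str = ""):
        self._stats = {k: (float(m), float(s)) for k, (m, s) in stats.items()}
        self.provenance = provenance

    @classmethod
    def from_results(
        cls, results: Iterable[ExerciseResult] | pd.DataFrame, provenance: str = ""
    ) -> "ExerciseCohortStats":
        df = _as_frame(results)
        grouped = df.groupby("exercise_id")["raw_score"].agg(["mean", "std"])
        stats = {
            ex: (row["mean"], row["std"]) for ex, row in grouped.iterrows()
        }
        return cls(stats, provenance=provenance)

    def mean(self, exercise_id: str) -> float:
        return self._lookup(exercise_id)[0]

    def sd(self, exercise_id: str) -> float:
        return self._lookup(exercise_id)[1]

    def _lookup(self, exercise_id: str) -> tuple[float, float]:
        try:
            mean, sd = self._stats[exercise_id]
        except KeyError:
            raise UnknownExerciseError(
                f"no cohort distribution for exercise {exercise_id!r}"
            ) from None
        if not sd > 0:
            raise DegenerateDistributionError(
                f"cohort score distribution for {exercise_id!r} has zero spread"
            )
        return mean, sd

    def zscore(self, exercise_id: str, raw_score: float) -> float:
        mean, sd = self._lookup(exercise_id)
        return (raw_score - mean) / sd

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return dict(self._stats)

    def __contains__(self, exercise_id: str) -> bool:
        return exercise_id in self._stats

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ExerciseCohortStats) and self._stats == other._stats
        )


def comparable_score(result: ExerciseResult, cohort: ExerciseCohortStats) -> float:
    """Cohort-standardized score of one attempt (z against the cohort)."""
    return cohort.zscore(result.exercise_id, result.raw_score)


def _as_frame(results: Iterable[ExerciseResult] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    rows = [
        (r.participant_id, r.exercise_id, r.session_index, r.raw_score)
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "exercise_id", "session_index", "raw_score"]
    )


def domain_scores(
    results: Iterable[ExerciseResult] | pd.DataFrame,
    catalog: ExerciseCatalog,
    cohort: ExerciseCohortStats,
) -> dict[CognitiveDomain, float]:
    """Per-domain mean of one participant's comparable scores.

    Domains without any attempt are absent from the result.
    """
    df = _as_frame(results)
    if df.empty:
        return {}
    out: dict[CognitiveDomain, list[float]] = {}
    for row in df.itertuples(index=False):
        domain = catalog.exercise(row.exercise_id).domain
        out.setdefault(domain, []).append(cohort.zscore(row.exercise_id, row.raw_score))
    return {d: float(np.mean(v)) for d, v in out.items()}


@dataclass(frozen=True)
class DomainScoreBoard:
    """Domain scores for a cohort of participants.

    ``scores`` is indexed by participant id with one column per domain label;
    NaN marks a domain the participant never attempted.
    """

    scores: pd.DataFrame

    def target_zone_bounds(self) -> pd.Series:
        """75th-percentile bound per domain (linear interpolation)."""
        return self.scores.quantile(TARGET_ZONE_QUANTILE)

    def in_zone(self) -> pd.DataFrame:
        """Boolean frame: participant x domain, True when score >= bound."""
        return self.scores.ge(self.target_zone_bounds(), axis=1)

    def in_zone_fractions(self) -> pd.Series:
        """Fraction of scored participants in zone, per domain."""
        return self.in_zone().sum() / self.scores.notna().sum()


def build_score_board(
    results: Iterable[ExerciseResult] | pd.DataFrame,
    catalog: ExerciseCatalog,
    cohort: ExerciseCohortStats,
) -> DomainScoreBoard:
    """Build the cohort score board from a stream of results (any participants)."""
    df = _as_frame(results).copy()
    domain_of = {ex.id: ex.domain.value for ex in catalog.exercises}
    unknown = set(df["exercise_id"]) - set(domain_of)
    if unknown:
        raise UnknownExerciseError(f"exercise ids not in catalog: {sorted(unknown)}")
    mean = df["exercise_id"].map(lambda e: cohort.mean(e))
    sd = df["exercise_id"].map(lambda e: cohort.sd(e))
    df["z"] = (df["raw_score"] - mean) / sd
    df["domain"] = df["exercise_id"].map(domain_of)
    table = df.pivot_table(
        index="participant_id", columns="domain", values="z", aggfunc="mean"
    )
    ordered = [d.value for d in CognitiveDomain if d.value in table.columns]
    return DomainScoreBoard(scores=table[ordered])


@dataclass(frozen=True)
class FeedbackBar:
    """One bar of the performance feedback graph."""

    domain: CognitiveDomain
    score: float
    zone_bound: float
    in_zone: bool


def feedback_graph(
    board: DomainScoreBoard,
    participant_id: str,
    min_cohort: int = DEFAULT_MIN_COHORT,
) -> list[FeedbackBar]:
    """Per-domain feedback for one participant against the cohort target zone.

    Raises :class:`InsufficientCohortError` when fewer than ``min_cohort``
    participants have a score in a displayed domain.  The board is read-only:
    this function never mutates it.
    """
    if participant_id not in board.scores.index:
        raise KeyError(f"participant {participant_id!r} not on the score board")
    row = board.scores.loc[participant_id]
    bounds = board.target_zone_bounds()
    counts = board.scores.notna().sum()
    bars: list[FeedbackBar] = []
    for domain in CognitiveDomain:
        label = domain.value
        if label not in row.index or math.isnan(row[label]):
            continue
        if counts[label] < min_cohort:
            raise InsufficientCohortError(
                f"only {counts[label]} cohort scores in {label!r}; "
                f"need at least {min_cohort}"
            )
        score = float(row[label])
        bound = float(bounds[label])
        bars.append(
            FeedbackBar(domain=domain, score=score, zone_bound=bound,
                        in_zone=score >= bound)
        )
    return bars
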