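"""Cognitive profiles: baseline standardization, ranking, tiers and refreshes.

A participant's *cognitive profile* is their per-domain standardized score
vector together with the induced ranking from strengths (highest z) to
weaknesses (lowest z).  The top 2 ranked domains form the strength tier, the
next 2 the mid tier and the bottom 3 the weakness tier; exercises inherit a
difficulty classification from their domain's tier (strength -> easy,
mid -> medium, weakness -> hard).

The baseline profile standardizes each intake test against a normative
reference (means/SDs of a pilot-style reference population) and averages
z-scores when a domain is assessed by more than one instrument.  At session
boundaries 13, 19 and 25 the profile is refreshed from the participant's own
training performance over the preceding session range (1-12, 13-18, 19-24),
standardized per exercise against the comparison cohort and averaged per
domain; domains with no attempts in the range carry their previous score
forward.  Rank ties always break by the canonical domain order, so the whole
pipeline is deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalog import DOMAINS, AssessmentSpec, CognitiveDomain, ExerciseCatalog, ExerciseSpec
from .errors import IncompleteIntakeError, NormsLookupError, RefreshError
from .scoring import ExerciseCohortStats, ExerciseResult, SessionRecord

__all__ = [
    "Tier",
    "DifficultyTier",
    "TIER_SIZES",
    "NormativeReference",
    "CognitiveProfile",
    "standardize",
    "build_baseline_profile",
    "classify_exercise",
    "refresh_profile",
    "REFRESH_POINTS",
    "REFRESH_RANGES",
    "rank_domains",
    "assign_tiers",
]


class Tier(enum.Enum):
    STRENGTH = "strength"
    MID = "mid"
    WEAKNESS = "weakness"


class DifficultyTier(enum.Enum):
    EASY = "easy"
    MEDIUM = "medium"
    HARD = "hard"


#: Number of domains per tier, in rank order: ranks 1-2 are strengths,
#: 3-4 mid, 5-7 weaknesses.
TIER_SIZES: dict[Tier, int] = {Tier.STRENGTH: 2, Tier.MID: 2, Tier.WEAKNESS: 3}

_TIER_TO_DIFFICULTY = {
    Tier.STRENGTH: DifficultyTier.EASY,
    Tier.MID: DifficultyTier.MEDIUM,
    Tier.WEAKNESS: DifficultyTier.HARD,
}

#: Sessions at whose start the profile is refreshed, keyed to the preceding
#: session range the refresh draws on.
REFRESH_POINTS: tuple[int, ...] = (13, 19, 25)
REFRESH_RANGES: dict[int, range] = {
    13: range(1, 13),
    19: range(13, 19),
    25: range(19, 25),
}


@dataclass(frozen=True)
class NormativeReference:
    """Per-assessment location/scale of the reference population."""

    stats: Mapping[str, tuple[float, float]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for aid, (_, sd) in self.stats.items():
            if not sd > 0:
                raise ValueError(f"normative SD for {aid!r} must be positive")

    def mean(self, assessment_id: str) -> float:
        return self._lookup(assessment_id)[0]

    def sd(self, assessment_id: str) -> float:
        return self._lookup(assessment_id)[1]

    def _lookup(self, assessment_id: str) -> tuple[float, float]:
        try:
            return self.stats[assessment_id]
        except KeyError:
            raise NormsLookupError(
                f"assessment {assessment_id!r} missing from the normative reference"
            ) from None


def rank_domains(domain_z: Mapping[CognitiveDomain, float]) -> tuple[CognitiveDomain, ...]:
    """Domains sorted by z descending; ties break by canonical order."""
    return tuple(
        sorted(DOMAINS, key=lambda d: (-domain_z[d], d.canonical_index))
    )


def assign_tiers(ranking: Sequence[CognitiveDomain]) -> dict[CognitiveDomain, Tier]:
    """2/2/3 strength/mid/weakness partition along the ranking."""
    tiers: dict[CognitiveDomain, Tier] = {}
    cursor = 0
    for tier in (Tier.STRENGTH, Tier.MID, Tier.WEAKNESS):
        for domain in ranking[cursor : cursor + TIER_SIZES[tier]]:
            tiers[domain] = tier
        cursor += TIER_SIZES[tier]
    return tiers


@dataclass(frozen=True)
class CognitiveProfile:
    """Per-domain z-scores with the induced ranking and tier partition."""

    participant_id: str
    epoch: str
    domain_z: Mapping[CognitiveDomain, float]
    ranking: tuple[CognitiveDomain, ...]
    tiers: Mapping[CognitiveDomain, Tier]

    @classmethod
    def from_scores(
        cls, participant_id: str, epoch: str, domain_z: Mapping[CognitiveDomain, float]
    ) -> "CognitiveProfile":
        if set(domain_z) != set(DOMAINS):
            missing = [d.value for d in DOMAINS if d not in domain_z]
            raise IncompleteIntakeError(f"domains without scores: {missing}")
        ranking = rank_domains(domain_z)
        return cls(
            participant_id=participant_id,
            epoch=epoch,
            domain_z=dict(domain_z),
            ranking=ranking,
            tiers=assign_tiers(ranking),
        )

    def domains_in_tier(self, tier: Tier) -> tuple[CognitiveDomain, ...]:
        """Tier members in canonical domain order."""
        return tuple(d for d in DOMAINS if self.tiers[d] is tier)


def standardize(
    raw_score: float, assessment: AssessmentSpec, norms: NormativeReference
) -> float:
    """z-score of a raw test score against the normative reference."""
    return (raw_score - norms.mean(assessment.id)) / norms.sd(assessment.id)


def build_baseline_profile(
    test_scores: Mapping[str, float],
    norms: NormativeReference,
    catalog: ExerciseCatalog,
    participant_id: str = "participant",
) -> CognitiveProfile:
    """Baseline profile from one raw score per intake assessment.

    Each test is standardized against the norms; when a domain is assessed by
    several instruments their z-scores are averaged.  Every domain must be
    covered or :class:`IncompleteIntakeError` is raised.
    """
    domain_z: dict[CognitiveDomain, float] = {}
    for domain in DOMAINS:
        zs = [
            standardize(test_scores[a.id], a, norms)
            for a in catalog.assessments_for(domain)
            if a.id in test_scores
        ]
        if not zs:
            raise IncompleteIntakeError(
                f"no intake score for domain {domain.value!r}"
            )
        domain_z[domain] = float(np.mean(zs))
    return CognitiveProfile.from_scores(participant_id, "baseline", domain_z)


def classify_exercise(
    profile: CognitiveProfile, exercise: ExerciseSpec
) -> DifficultyTier:
    """Difficulty of an exercise for this participant, via its domain's tier."""
    return _TIER_TO_DIFFICULTY[profile.tiers[exercise.domain]]


def refresh_profile(
    profile: CognitiveProfile,
    own_records: Iterable[SessionRecord] | Iterable[ExerciseResult],
    cohort: ExerciseCohortStats,
    refresh_point: int,
    catalog: ExerciseCatalog,
) -> CognitiveProfile:
    """Refresh the profile from training performance in the preceding range.

    ``own_records`` may be session records or bare exercise results; only
    attempts whose session index lies in the range preceding ``refresh_point``
    count.  Each attempt's raw score is standardized against the cohort's
    per-exercise distribution, the z-scores are averaged per domain, and
    ranking/tiers are recomputed.  Domains without attempts in the range keep
    their previous score.
    """
    if refresh_point not in REFRESH_RANGES:
        raise ValueError(f"refresh point must be one of {REFRESH_POINTS}")
    session_range = REFRESH_RANGES[refresh_point]
    results: list[ExerciseResult] = []
    for rec in own_records:
        if isinstance(rec, SessionRecord):
            results.extend(rec.results)
        else:
            results.append(rec)
    in_range = [r for r in results if r.session_index in session_range]
    if not in_range:
        raise RefreshError(
            f"no attempts in sessions {session_range.start}-{session_range.stop - 1} "
            f"to refresh from"
        )
    per_domain: dict[CognitiveDomain, list[float]] = {}
    for r in in_range:
        domain = catalog.exercise(r.exercise_id).domain
        per_domain.setdefault(domain, []).append(cohort.zscore(r.exercise_id, r.raw_score))
    domain_z = {
        d: float(np.mean(per_domain[d])) if d in per_domain else float(profile.domain_z[d])
        for d in DOMAINS
    }
    return CognitiveProfile.from_scores(
        profile.participant_id, f"refresh-{refresh_point}", domain_z
    )
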