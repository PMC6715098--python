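"""Cognitive domains, training exercises and intake assessments.

The training battery is organized around seven cognitive domains.  Every
training exercise and every baseline assessment is mapped to exactly one
domain; exercises are inherently multidomain, so the mapping reflects the
predominant and unique cognitive skill an exercise requires.  The domain
enumeration order below is fixed and canonical: it is used throughout the
package as the deterministic tie-break order whenever two domains have equal
standing (e.g. equal z-scores in a cognitive profile).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import CatalogError

__all__ = [
    "CognitiveDomain",
    "DOMAINS",
    "ExerciseSpec",
    "AssessmentSpec",
    "ExerciseCatalog",
    "load_catalog",
    "default_catalog",
    "exercises_in_domains",
]


class CognitiveDomain(enum.Enum):
    """The seven trained cognitive domains, in canonical order.

    The member order is load-bearing: rank ties and tier assignment fall back
    to this order, so it must never be reshuffled.
    """

    VERBAL_MEMORY = "Verbal Memory"
    VISUAL_ATTENTION = "Visual Attention"
    VISUAL_MEMORY = "Visual Memory"
    VERBAL_EXECUTIVE = "Verbal Executive"
    VISUAL_EXECUTIVE = "Visual Executive"
    WORKING_MEMORY = "Working Memory"
    PROCESSING_SPEED = "Processing Speed"

    @property
    def canonical_index(self) -> int:
        """Position of this domain in the canonical (tie-break) order."""
        return DOMAINS.index(self)

    @classmethod
    def from_label(cls, label: str) -> "CognitiveDomain":
        """Parse a human-readable domain label (e.g. ``"Verbal Memory"``).

        Accepts the display label or the member name, case-insensitively.
        """
        norm = label.strip().lower().replace("_", " ")
        for member in cls:
            if norm in (member.value.lower(), member.name.lower().replace("_", " ")):
                return member
        raise CatalogError(f"unknown cognitive domain label: {label!r}")


DOMAINS: tuple[CognitiveDomain, ...] = tuple(CognitiveDomain)


@dataclass(frozen=True)
class ExerciseSpec:
    """One stand-alone training exercise.

    The exercise's internal game logic (stimuli, staircase difficulty, etc.)
    is a black box to this package; all that matters here is its stable id,
    display name and domain membership.
    """

    id: str
    display_name: str
    domain: CognitiveDomain


@dataclass(frozen=True)
class AssessmentSpec:
    """One baseline cognitive test feeding the intake profile."""

    id: str
    domain: CognitiveDomain
    source_name: str


@dataclass(frozen=True)
class ExerciseCatalog:
    """A validated set of exercises and assessments spanning the 7 domains.

    Invariants enforced at construction:

    * exercise ids are unique;
    * every domain contributes at least 3 exercises, and the two
      smallest domains together contribute at least 6 (so the six
      strength-tier slots of a session can be filled without repeating an
      exercise);
    * every domain is covered by at least one assessment.
    """

    exercises: tuple[ExerciseSpec, ...]
    assessments: tuple[AssessmentSpec, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ex in self.exercises:
            if ex.id in seen:
                raise CatalogError(f"duplicate exercise id: {ex.id!r}")
            seen.add(ex.id)
        counts = self.domain_counts()
        missing = [d.value for d in DOMAINS if counts.get(d, 0) == 0]
        if missing:
            raise CatalogError(f"domains without exercises: {missing}")
        low = sorted(counts.get(d, 0) for d in DOMAINS)
        if low[0] < 3:
            raise CatalogError("every domain needs at least 3 exercises")
        if low[0] + low[1] < 6:
            raise CatalogError(
                "the two smallest domains must jointly supply >= 6 exercises"
            )
        assessed = {a.domain for a in self.assessments}
        uncovered = [d.value for d in DOMAINS if d not in assessed]
        if uncovered:
            raise CatalogError(f"domains without assessments: {uncovered}")

    def domain_counts(self) -> dict[CognitiveDomain, int]:
        counts: dict[CognitiveDomain, int] = {}
        for ex in self.exercises:
            counts[ex.domain] = counts.get(ex.domain, 0) + 1
        return counts

    def exercises_for(self, domain: CognitiveDomain) -> tuple[ExerciseSpec, ...]:
        return tuple(ex for ex in self.exercises if ex.domain is domain)

    def assessments_for(self, domain: CognitiveDomain) -> tuple[AssessmentSpec, ...]:
        return tuple(a for a in self.assessments if a.domain is domain)

    def exercise(self, exercise_id: str) -> ExerciseSpec:
        for ex in self.exercises:
            if ex.id == exercise_id:
                return ex
        raise CatalogError(f"unknown exercise id: {exercise_id!r}")

    @property
    def exercise_ids(self) -> tuple[str, ...]:
        return tuple(ex.id for ex in self.exercises)


def _parse_exercise(row: Mapping, index: int) -> ExerciseSpec:
    try:
        domain = CognitiveDomain.from_label(str(row["domain"]))
    except CatalogError as exc:
        raise CatalogError(f"exercise row {index} ({row.get('name')!r}): {exc}") from exc
    except KeyError as exc:
        raise CatalogError(f"exercise row {index}: missing field {exc}") from exc
    name = str(row.get("name", row.get("id")))
    ex_id = str(row.get("id") or _slug(name))
    return ExerciseSpec(id=ex_id, display_name=name, domain=domain)


def _parse_assessment(row: Mapping, index: int) -> AssessmentSpec:
    try:
        domain = CognitiveDomain.from_label(str(row["domain"]))
    except CatalogError as exc:
        raise CatalogError(f"assessment row {index}: {exc}") from exc
    except KeyError as exc:
        raise CatalogError(f"assessment row {index}: missing field {exc}") from exc
    return AssessmentSpec(
        id=str(row["id"]),
        domain=domain,
        source_name=str(row.get("source", row["id"])),
    )


def _slug(name: str) -> str:
    return "_".join(name.strip().lower().split())


def load_catalog(source: str | Path | Mapping) -> ExerciseCatalog:
    """Load and validate an exercise catalog.

    ``source`` is either a path to a YAML file or an already-parsed mapping
    with ``exercises`` and ``assessments`` lists.  Loading is pure: the same
    source always yields an identical catalog.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        data = source
    if not isinstance(data, Mapping) or "exercises" not in data:
        raise CatalogError("catalog source must provide an 'exercises' list")
    exercises = tuple(
        _parse_exercise(row, i) for i, row in enumerate(data["exercises"], start=1)
    )
    assessments = tuple(
        _parse_assessment(row, i)
        for i, row in enumerate(data.get("assessments", ()), start=1)
    )
    return ExerciseCatalog(exercises=exercises, assessments=assessments)


@lru_cache(maxsize=1)
def default_catalog() -> ExerciseCatalog:
    """The packaged default catalog (35 exercises, 7 assessments)."""
    ref = resources.files("cogtrain.data").joinpath("catalog.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return load_catalog(data)


def exercises_in_domains(
    catalog: ExerciseCatalog, domains: Iterable[CognitiveDomain]
) -> tuple[ExerciseSpec, ...]:
    """All catalog exercises whose domain is in ``domains``, in catalog order."""
    wanted = set(domains)
    if not wanted:
        raise ValueError("domains must be a non-empty set")
    return tuple(ex for ex in catalog.exercises if ex.domain in wanted)
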