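from datetime import datetime, timezone

import pytest
from hypothesis import HealthCheck, settings

from cogtrain.catalog import DOMAINS, default_catalog
from cogtrain.profiles import CognitiveProfile, NormativeReference
from cogtrain.simulator import generate_normative_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

T0 = datetime(2024, 1, 1, 9, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def norms_and_stats(catalog):
    """Normative reference + per-exercise cohort distributions (n=100, fixed seed)."""
    return generate_normative_cohort(100, seed=7, catalog=catalog)


@pytest.fixture(scope="session")
def flat_norms(catalog):
    """Norms with mean 0, SD 1 for every assessment: raw scores are z-scores."""
    return NormativeReference(
        stats={a.id: (0.0, 1.0) for a in catalog.assessments}, provenance="flat"
    )


def profile_from_z(zs, participant_id="p1", epoch="baseline"):
    """Profile directly from a 7-vector of domain z-scores in canonical order."""
    return CognitiveProfile.from_scores(
        participant_id, epoch, dict(zip(DOMAINS, map(float, zs)))
    )


@pytest.fixture
def make_profile():
    return profile_from_z
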