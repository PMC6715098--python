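"""Virtual participants: normative cohorts, attempts, whole-module runs."""

import json

import numpy as np
import pytest
from scipy.stats import kendalltau

from cogtrain.adherence import FlagCause, Severity
from cogtrain.catalog import DOMAINS, default_catalog
from cogtrain.engine import TrainingEngine
from cogtrain.persistence import state_to_dict
from cogtrain.profiles import build_baseline_profile
from cogtrain.scoring import ExerciseCohortStats, comparable_score
from cogtrain.simulator import (
    VirtualParticipant,
    generate_normative_cohort,
    load_scenario,
    simulate_attempt,
    simulate_cohort,
    simulate_module,
)


def _participant(ability=0.0, **kwargs):
    defaults = dict(
        id="v1",
        latent_ability={d: ability for d in DOMAINS},
        learning_rate={d: 0.02 for d in DOMAINS},
        performance_noise_sd=0.3,
        seed=42,
    )
    defaults.update(kwargs)
    return VirtualParticipant(**defaults)


# --- normative cohort ---------------------------------------------------------


def test_normative_cohort_is_deterministic(catalog):
    a_norms, a_stats = generate_normative_cohort(100, seed=3, catalog=catalog)
    b_norms, b_stats = generate_normative_cohort(100, seed=3, catalog=catalog)
    assert a_norms.stats == b_norms.stats
    assert a_stats == b_stats


def test_cohort_needs_at_least_two_participants(catalog):
    with pytest.raises(ValueError):
        generate_normative_cohort(1, seed=0, catalog=catalog)


def test_doubling_ability_and_noise_scale_doubles_reference_sds(catalog):
    """Scaling oracle: the generator is affine in its scale parameters."""
    base, _ = generate_normative_cohort(
        80, seed=5, catalog=catalog, ability_sd=1.0, test_noise_sd=0.3
    )
    doubled, _ = generate_normative_cohort(
        80, seed=5, catalog=catalog, ability_sd=2.0, test_noise_sd=0.6
    )
    for a in catalog.assessments:
        assert doubled.sd(a.id) == pytest.approx(2.0 * base.sd(a.id), rel=1e-12)
        assert doubled.mean(a.id) == pytest.approx(2.0 * base.mean(a.id), abs=1e-9)


def test_vanishing_noise_leaves_between_subject_spread(catalog):
    noisy, _ = generate_normative_cohort(
        200, seed=9, catalog=catalog, ability_sd=1.0, test_noise_sd=0.0
    )
    # with no test noise the assessment SD is exactly the ability spread
    for a in catalog.assessments:
        assert 0.8 < noisy.sd(a.id) < 1.25


# --- single attempts ----------------------------------------------------------


def test_zero_noise_zero_learning_gives_identical_raw_scores(catalog):
    p = _participant(
        ability=1.0,
        learning_rate={d: 0.0 for d in DOMAINS},
        performance_noise_sd=0.0,
    )
    rng = np.random.default_rng(0)
    ex = catalog.exercises[0]
    raws = {simulate_attempt(p, ex, k, rng).raw_score for k in range(1, 6)}
    assert len(raws) == 1


def test_positive_learning_rate_increases_noise_free_scores(catalog):
    p = _participant(ability=0.0, performance_noise_sd=0.0)
    rng = np.random.default_rng(0)
    ex = catalog.exercises[0]
    raws = [simulate_attempt(p, ex, k, rng).raw_score for k in range(1, 10)]
    assert all(a < b for a, b in zip(raws, raws[1:]))


def test_ability_at_cohort_mean_scores_comparable_zero(catalog):
    """Chained with the scoring oracle: mean ability -> z = 0 under a
    matched noise-free cohort (the score map is affine inside its bounds)."""
    rng = np.random.default_rng(11)
    abilities = 0.5 * rng.standard_normal(50)
    from cogtrain.simulator import _raw_from_perf

    ex = catalog.exercises[0]
    raws = np.asarray(_raw_from_perf(abilities))
    stats = ExerciseCohortStats({ex.id: (raws.mean(), raws.std(ddof=1))})
    p = _participant(
        ability=float(abilities.mean()),
        learning_rate={d: 0.0 for d in DOMAINS},
        performance_noise_sd=0.0,
    )
    result = simulate_attempt(p, ex, 1, np.random.default_rng(0))
    assert comparable_score(result, stats) == pytest.approx(0.0, abs=1e-9)


def test_correct_fraction_tracks_latent_performance(catalog):
    rng = np.random.default_rng(1)
    ex = catalog.exercises[0]
    strong = np.mean([
        simulate_attempt(_participant(ability=2.0), ex, 1, rng).n_correct
        for _ in range(50)
    ])
    weak = np.mean([
        simulate_attempt(_participant(ability=-2.0), ex, 1, rng).n_correct
        for _ in range(50)
    ])
    assert strong > weak


# --- whole modules ------------------------------------------------------------


def _engine(catalog, seed=7):
    norms, stats = generate_normative_cohort(100, seed=seed, catalog=catalog)
    return TrainingEngine(catalog, norms, stats)


def test_compliant_participant_raises_no_flags(catalog):
    p = _participant(
        ability=3.0,
        learning_rate={d: 0.01 for d in DOMAINS},
        performance_noise_sd=0.0,
        overlong_prob=0.0,
        lapse_prob=0.0,
        seed=1,
    )
    log = simulate_module(p, _engine(catalog))
    assert log.sessions_completed == 30
    assert log.flags == []
    assert log.tickets == []


def test_constant_lapser_accumulates_absences_and_escalates(catalog):
    p = _participant(ability=2.5, performance_noise_sd=0.0, lapse_prob=1.0,
                     overlong_prob=0.0, seed=3)
    log = simulate_module(p, _engine(catalog))
    oranges = [f for f in log.flags if f.severity is Severity.ORANGE]
    assert all(f.cause is FlagCause.ABSENCE for f in oranges)
    # an absence flag after every inter-session gap actually taken
    assert len(oranges) >= log.sessions_completed - 1 >= 3
    escalations = [f for f in log.flags if f.cause is FlagCause.ADHERENCE_ESCALATION]
    assert len(escalations) == len(oranges) // 3
    # the first escalation lands on the third orange
    third_orange = oranges[2]
    assert escalations[0].timestamp >= third_orange.timestamp


def test_simulated_modules_are_byte_identical_under_a_seed(catalog):
    p = _participant(ability=0.5, seed=12345)
    log_a = simulate_module(p, _engine(catalog))
    log_b = simulate_module(p, _engine(catalog))
    dump_a = json.dumps(state_to_dict(_engine(catalog), log_a.state), sort_keys=True)
    dump_b = json.dumps(state_to_dict(_engine(catalog), log_b.state), sort_keys=True)
    assert dump_a == dump_b


def test_profile_refreshes_happen_at_the_range_boundaries(catalog):
    p = _participant(ability=0.0, lapse_prob=0.0, overlong_prob=0.0, seed=5)
    log = simulate_module(p, _engine(catalog))
    # enough sessions to cross every refresh boundary
    assert log.sessions_completed >= 25
    assert set(log.state.profiles) == {
        "baseline", "refresh-13", "refresh-19", "refresh-25"
    }
    # sessions before a boundary use the older profile epoch
    epochs = [
        plan_epoch
        for rec in log.state.records
        for plan_epoch in [
            "baseline" if rec.session_index <= 12
            else f"refresh-{13 if rec.session_index <= 18 else 19 if rec.session_index <= 24 else 25}"
        ]
    ]
    assert epochs == sorted(epochs, key=["baseline", "refresh-13", "refresh-19", "refresh-25"].index)


def test_more_lapsing_never_means_fewer_absence_flags(catalog):
    def absences(lapse_prob):
        total = 0
        for seed in range(5):
            p = _participant(ability=1.0, lapse_prob=lapse_prob,
                             overlong_prob=0.0, seed=seed)
            log = simulate_module(p, _engine(catalog))
            total += sum(1 for f in log.flags if f.cause is FlagCause.ABSENCE)
        return total

    a, b, c = absences(0.0), absences(0.5), absences(1.0)
    assert a <= b <= c
    assert a == 0


def test_parameter_recovery_of_the_latent_ability_ranking(catalog):
    """Baseline profiles recover 1-SD-separated latent rankings (tau >= 0.9)."""
    norms, _ = generate_normative_cohort(200, seed=21, catalog=catalog)
    rng = np.random.default_rng(22)
    spaced = np.arange(7, dtype=float) - 3.0  # separations of exactly 1 SD
    taus = []
    for _ in range(200):
        abilities = rng.permutation(spaced)
        scores = {
            a.id: abilities[a.domain.canonical_index] + 0.3 * rng.standard_normal()
            for a in catalog.assessments
        }
        profile = build_baseline_profile(scores, norms, catalog)
        zs = [profile.domain_z[d] for d in DOMAINS]
        tau, _p = kendalltau(abilities, zs)
        taus.append(tau)
    assert np.mean(taus) >= 0.9


# --- scenarios ----------------------------------------------------------------


def test_scenario_round_trip_and_cohort_run(catalog, tmp_path):
    scenario = load_scenario(
        {"name": "mini", "n_participants": 2, "seed": 13, "norms_n": 50,
         "lapse_prob": 0.0, "overlong_prob": 0.0}
    )
    engine, logs = simulate_cohort(scenario, catalog=catalog)
    assert len(logs) == 2
    assert all(log.sessions_completed == 30 for log in logs)
    # reproducible end to end
    engine2, logs2 = simulate_cohort(scenario, catalog=catalog)
    assert [log.summary() for log in logs] == [log.summary() for log in logs2]
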