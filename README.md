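# cogtrain

An adaptive delivery engine for multidomain computerized cognitive training
(CCT), modeled on the Brain Training System built for the Maintain Your
Brain (MYB) online dementia-prevention trial.  It is aimed at researchers
who design or study home-based CCT interventions and need the delivery
logic — profiling, scheduling, scoring, feedback and adherence triage — as
testable, reusable code rather than as a production web platform.

The package contains no exercise content and no trial data.  Exercises are
black boxes identified by a catalog (35 named exercises over 7 cognitive
domains); a virtual-participant simulator stands in for both the exercises
and the humans, so every component can be exercised end to end.

## What it implements

**Cognitive profile.** Eight baseline tests map onto seven domains (Verbal
Memory, Visual Attention, Visual Memory, Verbal Executive, Visual
Executive, Working Memory, Processing Speed).  Each test score *x* is
standardized against a normative reference, *z* = (*x* − μ)/σ, and domains
are ranked from strengths (highest *z*) to weaknesses (lowest *z*).  Ranks
1–2 form the strength tier, 3–4 the mid tier, 5–7 the weakness tier.

**"Sandwich" sessions.** Each of the 30 sessions in a 10-week module holds
17 slots: 6 easy (strength-tier domains), 4 medium (mid tier) and 7 hard
(weakness tier), arranged `E E M M M H H H E E M H H H H E E` so that easy
exercises open, relieve and close the session.  Slot filling is
pseudorandom without within-session repetition, reproducible from a seed.
Sessions cannot be skipped; the module window closes after 70 days; monthly
booster sessions follow for up to 3 years.

**Adaptive refreshes.** Before sessions 13, 19 and 25 the profile is
recomputed from the participant's own training scores over the preceding
session range, standardized per exercise against the comparison cohort and
averaged per domain — so the sandwich tracks training performance, not just
the intake battery.

**Scoring and feedback.** Per-exercise cohort z-scores make scores
comparable across exercises; domain scores are their per-domain means.  The
feedback graph shows each domain score against a target zone: at or above
the cohort's 75th percentile (the top performing 25%).

**Adherence triage.** Red flags for poor performance (more incorrect than
correct, zero correct, below a predefined level, ≥10% drop between
consecutive attempts of the same exercise); orange flags for poor adherence
(session > 90 min, absence ≥ 72 h); three oranges escalate to a red.  Red
flags open trainer tickets (open → assigned → resolved, with handover) and
trigger automatic participant emails capped at 1 per 72 hours.  A
"CheerSquad" of up to five friends/family is notified at training
milestones.  All emails are outbox events; nothing is sent.

**Simulator.** Virtual participants have per-domain latent abilities,
practice-driven learning rates, attempt noise and behavioral traits
(cadence, lapse and overlong-session probabilities).  They drive the whole
stack — intake, 30 sessions, refreshes, flags, tickets, notifications —
reproducibly from a seed.

## Worked example

```python
from cogtrain import (default_catalog, generate_normative_cohort,
                      build_baseline_profile)
from cogtrain.scheduler import make_session_plan, session_rng

catalog = default_catalog()
norms, cohort_stats = generate_normative_cohort(100, seed=7)  # pilot-style
scores = {
    "logos": 0.8, "cogstate_identification": -0.2,
    "visual_memory_composite": 0.1, "cbs_grammatical_reasoning": -1.1,
    "cbs_spatial_search": 0.4, "cogstate_one_back": 1.2,
    "cogstate_detection": -0.6,
}
profile = build_baseline_profile(scores, norms, catalog, "demo-participant")
for rank, d in enumerate(profile.ranking, 1):
    print(f"{rank}. {d.value:18s} z={profile.domain_z[d]:+.3f}"
          f"  [{profile.tiers[d].value}]")
```

prints the ranked profile (z is the intake score relative to the normative
cohort; the 2/2/3 tier split drives exercise difficulty):

```
1. Working Memory     z=+1.159  [strength]
2. Verbal Memory      z=+0.810  [strength]
3. Visual Executive   z=+0.248  [mid]
4. Visual Memory      z=+0.195  [mid]
5. Visual Attention   z=-0.183  [weakness]
6. Processing Speed   z=-0.535  [weakness]
7. Verbal Executive   z=-0.866  [weakness]
```

and the first sandwich session for that profile:

```python
plan = make_session_plan(profile, catalog, 1, session_rng(0, 1))
for i, (ex, tier) in enumerate(plan.slots, 1):
    print(f"slot {i:2d}  {tier.value:6s}  {ex.id}")
```

```
slot  1  easy    memo_pair
slot  2  easy    form_fever
slot  3  medium  escalator
...
slot 17  easy    mixed_memories
```

Slots 1–2 are always strength-domain (easy) exercises; the session tallies
6 easy / 4 medium / 7 hard with no exercise repeated.

There is also a CLI (`cogtrain norms / intake / plan / advance / report /
simulate`) for running the same lifecycle from files; `cogtrain simulate`
runs a whole scenario of virtual participants and writes results, event
logs and summaries as CSV/JSONL.

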