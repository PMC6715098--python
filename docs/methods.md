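# Methods

This note documents the models, rules and numerical conventions behind
`cogtrain`, the design choices made where the delivery logic was genuinely
open, and what the simulator does and does not emulate.

## Profile model

The cognitive profile is a 7-vector of standardized domain scores.  At
intake, each of the 8 tests is converted to z = (raw − μ)/σ against a
normative reference; when a domain has several instruments (Visual Memory:
two instruments treated as one composite record) their z-scores are
averaged, so every domain contributes exactly one number.  Domains are
ranked by z descending.  **Ties break by the canonical domain order**
(Verbal Memory, Visual Attention, Visual Memory, Verbal Executive, Visual
Executive, Working Memory, Processing Speed) — an arbitrary but fixed
convention that makes the whole pipeline deterministic.

**Tier partition 2/2/3.**  The tier sizes (2 strength, 2 mid, 3 weakness)
are a design choice of this package: three tiers are required by the
easy/medium/hard classification; 2 strength domains are the largest number
for which the 6 easy slots can always be filled without within-session
repetition (the two smallest domains offer 3 + 3 = 6 exercises); and any 3
weakness domains offer at least 3 + 3 + 4 = 10 ≥ 7 hard exercises.  The
catalog validator enforces exactly these feasibility conditions so the
guarantee survives user-supplied catalogs.

**Refreshes.**  The profile is refreshed before sessions 13, 19 and 25
from the participant's attempts in the preceding session range (1–12,
13–18, 19–24).  We interpret the refresh points as *session indices*, not
calendar weeks: the session-range formulation is the operational one, and
a week-based reading conflicts with the 3-sessions/week arithmetic.  The
refresh rule is: standardize each attempt's raw score against the
comparison cohort's per-exercise distribution, average per domain, re-rank
and re-tier.  Domains with no attempts in the range carry their previous
score forward.  No explicit "improvement" term is added: because scores
are cohort-relative, improving faster than the cohort raises the domain
score by construction.  The exact update formula was an open design point;
this one is chosen because it makes profile refreshing and performance
scoring a single shared computation.

**Comparison cohort for refreshes.**  Ideally the reference is the other
trial participants' attempts in the same session range.  The engine
accepts per-range distributions (`TrainingEngine(refresh_stats=...)`); its
fallback — used by the simulator and CLI — is the normative cohort's
first-attempt distributions.  With a fallback reference, cohort-wide
practice gains appear as positive drift in everyone's refreshed scores;
ranking and tiers, which are what the scheduler consumes, are unaffected
by a shared shift within a domain.

## Sandwich scheduling

Only the opening of the positional pattern (2 easy, 3 medium, 3 hard) and
the 6/4/7 totals with easy blocks at the beginning, middle and end are
fixed by the design; the full 17-slot sequence is this package's canonical
completion: `E E M M M H H H E E M H H H H E E`.  Slot filling draws
pseudorandomly, without within-session replacement, from the exercises of
the tier's domains.  Draws across sessions are independent (no balancing
memory); a round-robin exposure balancer would be a reasonable alternative
but is not implemented.

Randomness is structured for reproducibility: the per-session stream is
`default_rng(SeedSequence((module_seed, session_index)))`, so any session's
plan can be regenerated in isolation and save/load cannot lose generator
position.

The module window is exactly 70 days from the participant's module start.
The next session offered is always the lowest-index uncompleted one
(sessions cannot be skipped); after the window closes the module ends
regardless of progress.  Boosters are one standard sandwich session per
calendar month (day-of-month clamped in short months), up to 36 months;
their content uses the last refreshed profile.

## Scoring and feedback

Comparable scores are per-exercise cohort z-scores; domain scores are
per-domain means over a participant's attempts.  The feedback target zone
is the interval at or above the cohort's 75th percentile of domain scores,
computed with the linear-interpolation quantile (numpy default); *in zone*
means score ≥ bound.  Under this convention, a cohort of n distinct scores
has floor(n/4) or ceil(n/4) members in zone, and large simulated cohorts
sit at 25.0% per domain.  A zone is only reported for cohorts of at least
20 scored participants (configurable).

## Adherence rules and boundaries

* decrease in performance: raw ≤ (1 − 0.10) · previous raw, across two
  consecutive attempts of the same exercise in different sessions; the
  boundary is inclusive (a drop of exactly 10% flags).  The comparison is
  on the exercise's native scale and is skipped when the previous score is
  not positive (a relative decline from zero is undefined).
* below predefined level: raw < per-exercise minimum; the default level is
  10% of the native maximum score (100 of 1000) — the design names no
  value, so it is configuration with a documented default.
* overlong session: duration > 90 minutes, strict.
* absence: gap since the previous session's end ≥ 72 hours, inclusive.
  The asymmetry (strict vs inclusive) follows the phrasing of the two
  rules ("longer than 90 minutes" vs "absent for 72 hours").
* escalation: every 3rd orange flag since the last escalation produces an
  adherence red flag and resets the counter.

Orange flags notify trainers in-system only; red flags (including
escalations) open a ticket, alert all trainers and request an automatic
participant email.  Emails pass a throttle: one is emitted only if none
was emitted in the preceding 72 hours.  "At most 1 per 72-hour sliding
window" is measured over half-open windows [t, t + 72 h); with closed
windows two emails exactly 72 h apart would both be counted and the cap as
stated would be unsatisfiable.  Help-request acknowledgements are not
routed through this cap, which applies to automatic mail only.  All email
side effects are outbox events; nothing is transported.

Ticket lifecycle: open → assigned → resolved; re-assigning the current
owner is an idempotent no-op; handover between trainers happens via
transfer while assigned; every other transition (e.g. resolving an
unassigned ticket) raises.  The machine is closed under arbitrary action
sequences — model-checked exhaustively over short sequences in the tests.

CheerSquad milestones default to completion of sessions 1, 10, 20 and 30;
the milestone set is configurable because none is prescribed.

## Simulator

A virtual participant has per-domain latent ability *a* (population-SD
units), per-domain learning rate λ (score gain per attempt, default 0.02),
attempt noise σ (default 0.3), a session cadence (gap mean 56 h ≈ 3
sessions/week, SD 12 h, non-lapse gaps clipped below 72 h), an
overlong-session probability (default 0.05) and a lapse probability
(default 0.10; a lapse draws a gap of 72 h + Exp(24 h)).  Attempt
performance is perf = a + λ·(attempt − 1) + σε; the native raw score is
clip(500 + 150·perf, 0, 1000); correct counts are Binomial(20,
sigmoid(perf)), so better performance yields higher correct fractions.
Session durations are ~N(45, 8) minutes clipped to [20, 89], or 91 +
Exp(10) minutes for overlong sessions.  The noise SD may be set to 0 to
obtain the deterministic limit used in several tests.

The normative generator simulates a pilot-style reference cohort (default
n = 100): per-assessment means/SDs from ability + test noise, and
per-exercise first-attempt score distributions on the native scale.  It is
affine in its scale parameters, which the scaling tests exploit.

All draws descend from seeded `SeedSequence` streams keyed by (seed,
component); identical parameters and seed give byte-identical logs.

**What the simulator does not emulate.**  Within-exercise staircase
difficulty belongs to the black-box exercises and is absorbed into the
learning-rate term.  Latent abilities are stationary apart from practice
gains — no fatigue, forgetting, time-of-day or motivational dynamics — and
test/exercise noise is Gaussian and homoscedastic.  Passing tests
therefore demonstrate the correctness of the delivery logic under these
idealized conditions, not psychometric fidelity to any real test battery
or population.

## Problem sizes used in verification

The packaged checks run the schedule structure over a full 30-session
module (510 slots); the flag-storm throttle over 240 hourly red flags; the
target-zone fraction over a 10,000-participant simulated cohort (one
attempt per exercise, vectorized); and ability-ranking recovery over 200
simulated intakes with abilities spaced 1 population SD apart (mean
Kendall τ ≥ 0.9).  These sizes keep the whole suite in seconds while
leaving the stochastic checks comfortably stable.

## Known limitations

* The exercise catalog ships the published 35-name table although the
  accompanying prose counts 34 exercises; which entry (if any) was merged
  or dropped in production is unknowable from the available description.
* The refresh weighting between cohort-relative level and improvement is a
  documented choice (pure cohort-relative level), not a reproduction of an
  unpublished production formula.
* Booster content, milestone sets, the predefined score levels and the
  tier sizes are configurable defaults chosen here; the source design
  leaves them unspecified.
* The engine is single-participant per state object; cohort-level flows
  (shared refresh references updated online) are left to the caller.
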